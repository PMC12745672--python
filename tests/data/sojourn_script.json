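{
  "version": 1,
  "description": "one consumer resident 2 time units in the lower-left cell, then 1 unit in the lower-right cell of a 2x2 grid",
  "horizon": 3.0,
  "individuals": [{"id": 0, "x": 0.25, "y": 0.25}],
  "particles": [],
  "script": [{"time": 2.0, "kind": "move", "actor": 0, "x": 0.75, "y": 0.25}],
  "expected_weights": {"grid": 2, "cells": {"0,0": 0.6666666666666666, "1,0": 0.3333333333333333}}
}
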