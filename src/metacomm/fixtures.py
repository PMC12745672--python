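"""Deterministic small-scale fixtures for testing every analysis stage.

Two generators are provided:

* :func:`make_planted_adjacency` builds block-structured adjacency matrices
  with a known ground-truth partition, spanning the three qualitative
  regimes of metacommunity organisation: fully isolated local communities
  (no between-block weight), the classical metacommunity (strong blocks with
  some between-block weight), and an unstructured community continuum
  (within = between, no recoverable blocks).

* :func:`make_toy_eventlog` assembles a valid :class:`~metacomm.simulator.EventLog`
  from a hand-written script of timed events, so that the space-use,
  interaction and offspring estimators can be unit-tested against sojourn
  times and pair rules computed by hand, without running the stochastic
  engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adjacency import AdjacencyMatrix
from .communities import Partition
from .simulator import (
    EVENT_COLUMNS,
    EventLog,
    GUILD_CONSUMER,
    INDIVIDUAL_COLUMNS,
    RESOURCE_COLUMNS,
    Snapshot,
)


@dataclass(frozen=True)
class PlantedPartitionSpec:
    """Block-model specification: sizes, weights, additive noise, seed."""

    block_sizes: tuple = (8, 8, 8)
    within: float = 1.0
    between: float = 0.0
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.within >= self.between >= 0:
            raise ValueError("need within >= between >= 0")
        if self.noise < 0:
            raise ValueError("noise must be non-negative")


def make_planted_adjacency(spec: PlantedPartitionSpec) -> tuple:
    """Symmetric planted-partition matrix plus its ground-truth labels.

    Entry (i, j) is ``within`` inside a block and ``between`` across blocks,
    plus symmetric uniform noise on ``[0, noise]``.  Returns
    ``(AdjacencyMatrix, Partition)``.
    """
    labels = np.concatenate([np.full(sz, k)
                             for k, sz in enumerate(spec.block_sizes)])
    n = len(labels)
    w = np.where(labels[:, None] == labels[None, :], spec.within, spec.between
                 ).astype(float)
    if spec.noise > 0:
        rng = np.random.default_rng([spec.seed, 0xB10C])
        e = rng.uniform(0, spec.noise, size=(n, n))
        w += np.triu(e, 1) + np.triu(e, 1).T
    np.fill_diagonal(w, 1.0)
    ids = tuple(range(n))
    adj = AdjacencyMatrix("space", ids, w, symmetric=True,
                          provenance={"planted": True, "seed": spec.seed})
    truth = Partition(ids, labels, source="planted")
    return adj, truth


def make_toy_eventlog(script, individuals, particles=None,
                      horizon: float = 1.0, t0: float = 0.0) -> EventLog:
    """Build an EventLog from a hand-written script.

    Parameters
    ----------
    script:
        list of dicts with keys among :data:`~metacomm.simulator.EVENT_COLUMNS`
        (``time`` and ``kind`` and ``actor`` required; the rest default to
        -1 / NaN).  Times must be non-decreasing and lie in
        ``[t0, t0 + horizon]``.
    individuals:
        list of dicts for the initial state (``id``, ``x``, ``y`` required;
        ``species`` defaults to 0, ``guild`` to consumer, ``host_id`` to -1).
    particles:
        list of dicts (``id``, ``x``, ``y``; ``rtype`` defaults to 0,
        ``created_at`` to ``t0``) describing every resource particle
        referenced by consume events.
    """
    ind_rows = []
    for d in individuals:
        ind_rows.append((int(d["id"]), int(d.get("species", 0)),
                         int(d.get("guild", GUILD_CONSUMER)),
                         float(d["x"]), float(d["y"]),
                         int(d.get("host_id", -1)), float(d.get("born_at", t0))))
    ind = pd.DataFrame(ind_rows, columns=INDIVIDUAL_COLUMNS)

    part_rows = []
    for d in (particles or []):
        part_rows.append((int(d["id"]), int(d.get("rtype", 0)),
                          float(d["x"]), float(d["y"]),
                          float(d.get("created_at", t0))))
    parts = pd.DataFrame(part_rows, columns=RESOURCE_COLUMNS)

    rows = []
    last_t = t0
    known = set(ind.id.tolist())
    consumed: set = set()
    for d in script:
        t = float(d["time"])
        kind = d["kind"]
        if t < last_t:
            raise ValueError("script times must be non-decreasing")
        if not t0 <= t <= t0 + horizon:
            raise ValueError("script event outside the log horizon")
        last_t = t
        actor = int(d["actor"])
        if kind == "birth":
            known.add(actor)
        elif actor not in known:
            raise ValueError(f"event for unknown individual {actor}")
        if kind == "consume":
            pid = int(d["object"])
            if pid in consumed:
                raise ValueError(f"particle {pid} consumed twice")
            if len(parts) and pid not in set(parts.id.tolist()):
                raise ValueError(f"consume references unknown particle {pid}")
            consumed.add(pid)
        rows.append((t, kind, actor, int(d.get("object", -1)),
                     float(d.get("x", np.nan)), float(d.get("y", np.nan)),
                     int(d.get("species", -1)), int(d.get("parent", -1))))
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)

    full_parts = parts.copy()
    full_parts["consumed_by"] = -1
    full_parts["consumed_at"] = np.nan
    snap = Snapshot(time=t0, individuals=ind, resources=parts)
    return EventLog(t0=t0, horizon=horizon, events=events,
                    particles=full_parts, initial=snap)
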