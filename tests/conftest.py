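"""Shared helpers: hand-built configs and snapshots for engine tests."""

import numpy as np
import pandas as pd
import pytest

from metacomm.landscape import Landscape, LandscapeParams, NicheMatrix, make_landscape
from metacomm.simulator import (
    INDIVIDUAL_COLUMNS,
    RESOURCE_COLUMNS,
    RateModel,
    SimConfig,
    Snapshot,
)


def make_rates(n_species=2, *, m=0.0, sigma=0.05, d=0.0, rc=0.05, b=0.0,
               c=8.0, tau=2.0, **parasite_kw):
    """Uniform-rate model with everything overridable, parasites optional."""
    kw = dict(
        move_rate=np.full(n_species, float(m)),
        sigma=np.full(n_species, float(sigma)),
        death_rate=np.full(n_species, float(d)),
        consumption_radius=np.full(n_species, float(rc)),
        birth_prob=np.full(n_species, float(b)),
        contact_rate=float(c),
        resource_lifetime=float(tau),
    )
    kw.update(parasite_kw)
    return RateModel(**kw)


def make_mini_config(n_species=2, n_types=1, rate=0.0, usage=None, **rate_kw):
    """Homogeneous-landscape config for small hand-built experiments."""
    land = make_landscape(
        "homogeneous", LandscapeParams(n_types=n_types, rate_per_type=rate),
        seed=0)
    if usage is None:
        usage = np.ones((n_species, n_types), dtype=bool)
    return SimConfig(land, NicheMatrix(np.asarray(usage, dtype=bool)),
                     make_rates(n_species, **rate_kw))


def snap_of(individuals, resources=None, time=0.0):
    """Snapshot from lists of tuples matching the canonical column orders."""
    ind = pd.DataFrame(individuals, columns=INDIVIDUAL_COLUMNS)
    res = pd.DataFrame(resources or [], columns=RESOURCE_COLUMNS)
    return Snapshot(time=time, individuals=ind, resources=res)


def consumer(i, species=0, x=0.5, y=0.5):
    return (i, species, 0, x, y, -1, 0.0)


def parasite(i, species, host, x=0.5, y=0.5):
    return (i, species, 1, x, y, host, 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
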