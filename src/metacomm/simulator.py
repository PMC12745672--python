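"""Continuous-space, continuous-time agent-based metacommunity engine.

The model follows individual consumers (and optionally parasites) on the unit
torus.  Consumers move by kernel jumps, die at a base hazard, and consume
resource particles that lie within their consumption radius and that their
species can use; every consumption triggers a birth with a fixed probability,
with the offspring placed by the same (wrapped Gaussian) kernel around the
parent.  Parasites ride on consumer hosts, raise the host's death hazard, and
transmit to susceptible in-range hosts of species in their host range; a
parasite dies with its host (parasites are not free-living).

Simulation is an exact next-event realisation of the competing hazards
(Anderson's modified next-reaction formulation).  Every individual owns its
own random stream, keyed by its lineage, and resource production owns a
separate stream.  Consequently a *treatment* run in which one focal individual
is deleted before time zero consumes exactly the same random numbers for every
other individual as the paired *control* run: individuals that are dynamically
uncoupled from the focal produce bit-identical trajectories, which is what
makes the removal-based fitness-influence estimator well defined at finite
replicate numbers.

The module exposes:

* :func:`run` -- simulate an arbitrary initial state for a fixed horizon;
* :func:`run_to_stationarity` -- burn in from a dispersed initial condition
  until the total-abundance trend passes a slope diagnostic, then freeze a
  :class:`Snapshot`;
* :func:`run_replicate` / :func:`removal_replicate` -- replicate (and paired
  removal) simulations from a fixed snapshot;
* :func:`offspring_count` and :func:`ancestral_offspring_counts` -- fitness
  read-outs from an :class:`EventLog`.
"""

from __future__ import annotations

import heapq
import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import (
    DOMAIN_SIZE,
    Landscape,
    NicheMatrix,
    PARTICLE_COLUMNS,
    default_niche,
    sample_resource_events,
    torus_distance,
    wrap,
)

GUILD_CONSUMER = 0
GUILD_PARASITE = 1


def derive_seed(master: int, *idx: int) -> int:
    """Counter-based seed derivation: one master seed fans out to substreams.

    Deterministic, collision-resistant (hashes through a PRNG state), and the
    result stays below 2**31 so it can be passed anywhere an int seed goes.
    """
    return int(np.random.default_rng([int(master), *map(int, idx)])
               .integers(2**31))

#: fixed column order for event tables (and their TSV form)
EVENT_COLUMNS = ["time", "kind", "actor", "object", "x", "y", "species", "parent"]


class ExtinctionError(RuntimeError):
    """All individuals died during a run that required persistence."""


class StationarityError(RuntimeError):
    """Burn-in failed to reach an (approximately) stationary abundance."""


# ---------------------------------------------------------------------------
# model parameterisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateModel:
    """Per-species demographic and movement rates.

    Consumer arrays are indexed by consumer species; the parasite block is
    optional (``host_range is None`` disables the parasite layer).

    Units: rates are per individual per unit time; radii and kernel scales are
    in arena units (the arena is the unit square).
    """

    move_rate: np.ndarray          # m, relocation rate
    sigma: np.ndarray              # movement / natal dispersal kernel scale
    death_rate: np.ndarray         # d, base death hazard
    consumption_radius: np.ndarray  # r_c
    birth_prob: np.ndarray         # b, P(birth | consumption)
    contact_rate: float = 8.0      # c, hazard per in-range usable particle
    resource_lifetime: float = 2.0  # tau_R, particle expiry

    # parasite layer
    parasite_death: np.ndarray | None = None   # per parasite species
    transmission_radius: float = 0.10          # r_t
    transmission_rate: float = 3.0             # beta, hazard per in-range host
    virulence: float = 0.15                    # delta, added host death hazard
    host_range: np.ndarray | None = None       # (parasite sp, host sp) bool

    def __post_init__(self):
        for name in ("move_rate", "sigma", "death_rate",
                     "consumption_radius", "birth_prob"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if self.parasite_death is not None:
            object.__setattr__(self, "parasite_death",
                               np.asarray(self.parasite_death, dtype=float))
        if self.host_range is not None:
            object.__setattr__(self, "host_range",
                               np.asarray(self.host_range, dtype=bool))
        arrs = [self.move_rate, self.sigma, self.death_rate,
                self.consumption_radius, self.birth_prob]
        if any((a < 0).any() for a in arrs) or self.contact_rate < 0:
            raise ValueError("all rates must be non-negative")
        if self.has_parasites and self.virulence <= 0:
            raise ValueError("parasite virulence (delta) must be positive")

    @property
    def n_species(self) -> int:
        return len(self.death_rate)

    @property
    def has_parasites(self) -> bool:
        return self.host_range is not None

    @property
    def n_parasite_species(self) -> int:
        return 0 if self.host_range is None else self.host_range.shape[0]


#: short / long dispersal kernel scales; their ratio of 10 separates the
#: movement regimes by an order of magnitude, and the long scale stays below
#: the patch spacing so that long-range species remain spatially structured
#: rather than globally mixed on the unit arena.
SIGMA_SHORT = 0.006
SIGMA_LONG = 0.06


def default_rates(n_species: int = 8, dispersal: str = "mixed",
                  parasites: bool = False, n_parasite_species: int = 3,
                  **overrides) -> RateModel:
    """Standard rate set for the consumer-resource (and host-parasite) model.

    ``dispersal`` selects the movement regime: ``short`` (all species use the
    short kernel), ``long`` (all long), or ``mixed`` (first half of the
    species short, second half long).
    """
    if dispersal == "short":
        sigma = np.full(n_species, SIGMA_SHORT)
    elif dispersal == "long":
        sigma = np.full(n_species, SIGMA_LONG)
    elif dispersal == "mixed":
        sigma = np.where(np.arange(n_species) < n_species // 2,
                         SIGMA_SHORT, SIGMA_LONG)
    else:
        raise ValueError(f"unknown dispersal regime {dispersal!r}")

    kw = dict(
        move_rate=np.full(n_species, 1.5),
        sigma=sigma,
        death_rate=np.full(n_species, 0.3),
        consumption_radius=np.full(n_species, 0.08),
        birth_prob=np.full(n_species, 0.5),
        contact_rate=8.0,
        resource_lifetime=2.0,
    )
    if parasites:
        # parasite q can infect hosts {2q, .., 2q+3} mod S: every parasite
        # pair shares some but not all hosts (partial host overlap).
        hr = np.zeros((n_parasite_species, n_species), dtype=bool)
        for q in range(n_parasite_species):
            for k in range(4):
                hr[q, (2 * q + k) % n_species] = True
        kw.update(
            parasite_death=np.full(n_parasite_species, 0.35),
            transmission_radius=0.10,
            transmission_rate=3.0,
            virulence=0.15,
            host_range=hr,
        )
    kw.update(overrides)
    return RateModel(**kw)


@dataclass(frozen=True)
class SimConfig:
    """Bundle of landscape, niche and rates defining one scenario."""

    landscape: Landscape
    niche: NicheMatrix
    rates: RateModel

    def __post_init__(self):
        if self.niche.n_species != self.rates.n_species:
            raise ValueError("niche and rate model disagree on species count")
        if self.niche.n_types != self.landscape.n_types:
            raise ValueError("niche and landscape disagree on resource types")

    SCHEMA_VERSION = 1

    def to_yaml(self, path) -> None:
        import yaml

        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.astype(float).tolist() if v.dtype != bool \
                    else v.astype(int).tolist()
            return v

        payload = {
            "schema_version": self.SCHEMA_VERSION,
            "landscape": self.landscape.to_dict(),
            "niche": {"usage": self.niche.usage.astype(int).tolist()},
            "rates": {k: _clean(v) for k, v in vars(self.rates).items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("schema_version") != cls.SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema "
                             f"{d.get('schema_version')!r}")
        rk = dict(d["rates"])
        if rk.get("host_range") is not None:
            rk["host_range"] = np.array(rk["host_range"], dtype=bool)
        return cls(
            landscape=Landscape.from_dict(d["landscape"]),
            niche=NicheMatrix(np.array(d["niche"]["usage"], dtype=bool)),
            rates=RateModel(**rk),
        )


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

INDIVIDUAL_COLUMNS = ["id", "species", "guild", "x", "y", "host_id", "born_at"]
RESOURCE_COLUMNS = ["id", "rtype", "x", "y", "created_at"]


@dataclass(frozen=True)
class Snapshot:
    """Frozen metacommunity state: the common initial condition for replicates.

    Contains no random-generator state; replicate runs differ only through
    the seeds they are given.
    """

    time: float
    individuals: pd.DataFrame  # INDIVIDUAL_COLUMNS
    resources: pd.DataFrame    # RESOURCE_COLUMNS

    def __post_init__(self):
        ind = self.individuals.astype(
            {"id": np.int64, "species": np.int64, "guild": np.int64,
             "x": float, "y": float, "host_id": np.int64, "born_at": float})
        object.__setattr__(self, "individuals", ind)
        res = self.resources.astype(
            {"id": np.int64, "rtype": np.int64, "x": float, "y": float,
             "created_at": float})
        object.__setattr__(self, "resources", res)
        if len(ind):
            paras = ind[ind.guild == GUILD_PARASITE]
            if not paras.host_id.isin(ind.id).all():
                raise ValueError("parasite references a host absent from snapshot")

    @property
    def ids(self) -> np.ndarray:
        return self.individuals.id.to_numpy()

    @property
    def consumer_ids(self) -> np.ndarray:
        ind = self.individuals
        return ind.loc[ind.guild == GUILD_CONSUMER, "id"].to_numpy()

    @property
    def parasite_ids(self) -> np.ndarray:
        ind = self.individuals
        return ind.loc[ind.guild == GUILD_PARASITE, "id"].to_numpy()

    def to_json(self, path) -> None:
        payload = {
            "time": self.time,
            "individuals": self.individuals[INDIVIDUAL_COLUMNS].to_dict("records"),
            "resources": self.resources[RESOURCE_COLUMNS].to_dict("records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "Snapshot":
        with open(path) as fh:
            d = json.load(fh)
        ind = pd.DataFrame(d["individuals"], columns=INDIVIDUAL_COLUMNS)
        res = pd.DataFrame(d["resources"], columns=RESOURCE_COLUMNS)
        return cls(time=d["time"], individuals=ind, resources=res)


@dataclass(frozen=True)
class EventLog:
    """Time-ordered event record of one simulation run.

    ``events`` uses :data:`EVENT_COLUMNS`; ``particles`` records every
    resource particle that existed during the run (snapshot resources plus
    production), so that consume events can be resolved to a resource type.
    ``initial`` is the state the run started from, needed to replay the
    piecewise-constant location process.
    """

    t0: float
    horizon: float
    events: pd.DataFrame
    particles: pd.DataFrame
    initial: Snapshot
    extinct: bool = False

    def to_tsv(self, path) -> None:
        self.events[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)

    def births(self) -> pd.DataFrame:
        return self.events[self.events.kind == "birth"]


def offspring_count(log: EventLog, individual: int,
                    window: tuple | None = None) -> int:
    """Number of birth events parented directly by ``individual``.

    ``window`` is an optional (start, end) time interval (inclusive bounds)
    within the log horizon.
    """
    b = log.births()
    sel = b.parent == individual
    if window is not None:
        lo, hi = window
        if lo < log.t0 or hi > log.t0 + log.horizon:
            raise ValueError("window exceeds the log horizon")
        sel &= (b.time >= lo) & (b.time <= hi)
    return int(sel.sum())


def ancestor_map(log: EventLog) -> dict:
    """Map every individual in the log to its snapshot-founder ancestor.

    Snapshot individuals map to themselves; individuals born during the run
    map to the snapshot individual at the root of their parent chain.
    """
    roots = {int(i): int(i) for i in log.initial.ids}
    b = log.births()
    # births are time ordered, so a parent is always resolved first
    for child, parent in zip(b.actor.to_numpy(), b.parent.to_numpy()):
        roots[int(child)] = roots.get(int(parent), int(parent))
    return roots


def ancestral_offspring_counts(log: EventLog, ids: Sequence[int]) -> np.ndarray:
    """Birth events credited to each snapshot individual's lineage.

    Every birth is credited to the snapshot ancestor of its parent, so that
    reproduction by replicate-born descendants still counts towards the
    founder's fitness read-out.
    """
    roots = ancestor_map(log)
    pos = {int(i): k for k, i in enumerate(ids)}
    out = np.zeros(len(ids), dtype=float)
    for parent in log.births().parent.to_numpy():
        r = roots.get(int(parent))
        if r is not None and r in pos:
            out[pos[r]] += 1
    return out


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

_MOVE, _DEATH, _ACT = 0, 1, 2  # channel columns; _ACT = consume | transmit


def _tdist2(x0, y0, xs, ys):
    """Squared toroidal distance for coordinates already wrapped to [0, 1)."""
    dx = np.abs(xs - x0)
    dx = np.minimum(dx, 1.0 - dx)
    dy = np.abs(ys - y0)
    dy = np.minimum(dy, 1.0 - dy)
    return dx * dx + dy * dy


# Candidate searches run once or twice per event and dominate the engine's
# cost; they are compiled with numba when available and fall back to the
# equivalent numpy expressions otherwise.
try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None

if _njit is not None:
    @_njit(cache=True)
    def _count_in_range(x0, y0, xs, ys, a, b, r2):
        m = 0
        for k in range(xs.shape[0]):
            if a[k] and b[k]:
                dx = abs(xs[k] - x0)
                if dx > 0.5:
                    dx = 1.0 - dx
                dy = abs(ys[k] - y0)
                if dy > 0.5:
                    dy = 1.0 - dy
                if dx * dx + dy * dy <= r2:
                    m += 1
        return m

    @_njit(cache=True)
    def _idx_in_range(x0, y0, xs, ys, a, b, r2):
        out = np.empty(xs.shape[0], np.int64)
        m = 0
        for k in range(xs.shape[0]):
            if a[k] and b[k]:
                dx = abs(xs[k] - x0)
                if dx > 0.5:
                    dx = 1.0 - dx
                dy = abs(ys[k] - y0)
                if dy > 0.5:
                    dy = 1.0 - dy
                if dx * dx + dy * dy <= r2:
                    out[m] = k
                    m += 1
        return out[:m]

    @_njit(cache=True)
    def _sus_counts(hx, hy, psp, cx, cy, csp, host_range, r2):
        out = np.zeros(hx.shape[0], np.float64)
        for i in range(hx.shape[0]):
            cnt = 0
            for k in range(cx.shape[0]):
                if host_range[psp[i], csp[k]]:
                    dx = abs(cx[k] - hx[i])
                    if dx > 0.5:
                        dx = 1.0 - dx
                    dy = abs(cy[k] - hy[i])
                    if dy > 0.5:
                        dy = 1.0 - dy
                    if dx * dx + dy * dy <= r2:
                        cnt += 1
            out[i] = cnt
        return out

    @_njit(cache=True)
    def _idx_in_range_r(x0, y0, xs, ys, a, b, r2s):
        out = np.empty(xs.shape[0], np.int64)
        m = 0
        for k in range(xs.shape[0]):
            if a[k] and b[k]:
                dx = abs(xs[k] - x0)
                if dx > 0.5:
                    dx = 1.0 - dx
                dy = abs(ys[k] - y0)
                if dy > 0.5:
                    dy = 1.0 - dy
                if dx * dx + dy * dy <= r2s[k]:
                    out[m] = k
                    m += 1
        return out[:m]
else:  # pragma: no cover - exercised only without numba
    def _count_in_range(x0, y0, xs, ys, a, b, r2):
        return int(np.count_nonzero(a & b & (_tdist2(x0, y0, xs, ys) <= r2)))

    def _idx_in_range(x0, y0, xs, ys, a, b, r2):
        return np.flatnonzero(a & b & (_tdist2(x0, y0, xs, ys) <= r2))

    def _idx_in_range_r(x0, y0, xs, ys, a, b, r2s):
        return np.flatnonzero(a & b & (_tdist2(x0, y0, xs, ys) <= r2s))

    def _sus_counts(hx, hy, psp, cx, cy, csp, host_range, r2):
        d2 = _tdist2(hx[:, None], hy[:, None], cx[None, :], cy[None, :])
        ok = (d2 <= r2) & host_range[psp][:, csp]
        return ok.sum(axis=1).astype(float)


def _sample_production(config: SimConfig, snapshot: Snapshot,
                       horizon: float, seed: int) -> pd.DataFrame:
    """Production stream for one run; shareable across a removal sweep."""
    res = snapshot.resources
    return sample_resource_events(config.landscape, horizon, seed,
                                  t0=float(snapshot.time),
                                  id_start=(int(res.id.max()) + 1
                                            if len(res) else 0))


class _Engine:
    """Next-reaction simulation of one run.  Internal; use the module API."""

    def __init__(self, config: SimConfig, snapshot: Snapshot, horizon: float,
                 seed: int, exclude: Iterable[int] = (),
                 record_log: bool = True,
                 production: pd.DataFrame | None = None):
        if horizon < 0:
            raise ValueError("horizon must be non-negative")
        self.cfg = config
        self.rates = config.rates
        self.niche = config.niche
        self.seed = int(seed)
        self.t0 = float(snapshot.time)
        self.t = self.t0
        self.horizon = float(horizon)
        self.record_log = record_log
        self.events: list = []
        self.abundance: list = []  # (t, n consumers alive)
        self.extinct = False

        exclude = set(int(i) for i in exclude)
        ind = snapshot.individuals
        keep = ~ind.id.isin(exclude)
        ind = ind[keep].reset_index(drop=True)

        n0 = len(ind)
        cap = max(4 * n0 + 64, 256)
        self.n = 0
        self.iid = np.zeros(cap, dtype=np.int64)
        self.species = np.zeros(cap, dtype=np.int64)
        self.guild = np.zeros(cap, dtype=np.int8)
        self.x = np.zeros(cap)
        self.y = np.zeros(cap)
        self.alive = np.zeros(cap, dtype=bool)
        self.host = np.full(cap, -1, dtype=np.int64)      # row index of host
        self.par = np.full(cap, -1, dtype=np.int64)       # row index of parasite
        self.rc = np.zeros(cap)
        self.sig = np.zeros(cap)
        self.cnt = np.zeros(cap, dtype=np.int64)          # in-range usable particles
        self.rngs: list = [None] * cap
        self.keys: list = [None] * cap
        self.birth_idx = np.zeros(cap, dtype=np.int64)
        # next-reaction channel state
        self.rate = np.zeros((cap, 3))
        self.P = np.zeros((cap, 3))
        self.T = np.zeros((cap, 3))
        self.tlast = np.zeros((cap, 3))
        self.tfire = np.full((cap, 3), np.inf)

        self.next_id = int(ind.id.max()) + 1 if n0 else 0

        # --- particles: snapshot resources + pre-sampled production stream
        res = snapshot.resources
        if production is not None:
            prod = production
        elif horizon > 0:
            prod = _sample_production(config, snapshot, horizon, seed)
        else:
            prod = pd.DataFrame(columns=PARTICLE_COLUMNS)
        self.pid = np.concatenate([res.id.to_numpy(dtype=np.int64),
                                   prod.id.to_numpy(dtype=np.int64)])
        self.px = np.concatenate([res.x.to_numpy(float), prod.x.to_numpy(float)])
        self.py = np.concatenate([res.y.to_numpy(float), prod.y.to_numpy(float)])
        self.ptype = np.concatenate([res.rtype.to_numpy(np.int64),
                                     prod.rtype.to_numpy(np.int64)])
        self.pcreate = np.concatenate([res.created_at.to_numpy(float),
                                       prod.created_at.to_numpy(float)])
        self.pexpire = self.pcreate + self.rates.resource_lifetime
        self.pactive = np.zeros(len(self.pid), dtype=bool)
        self.pconsumed_by = np.full(len(self.pid), -1, dtype=np.int64)
        self.pconsumed_at = np.full(len(self.pid), np.nan)
        self.usable = self.niche.usage  # (S, T) bool
        #: per-species particle usability, (S, n_particles)
        self.ok_by_species = np.ascontiguousarray(self.usable[:, self.ptype])
        #: per-type usability of each individual row, (T, cap)
        self.usable_by_type = np.zeros((self.niche.n_types, cap), dtype=bool)
        self.alive_cons = np.zeros(cap, dtype=bool)
        self.rc2 = np.zeros(cap)

        n_init = len(res)
        self.pactive[:n_init] = True
        self.expiry_heap = [(self.pexpire[k], k) for k in range(n_init)]
        heapq.heapify(self.expiry_heap)
        # production events sorted by time within prod; initial resources first
        self.prod_order = np.arange(n_init, len(self.pid))
        self.prod_ptr = 0

        # --- seed individuals (snapshot order defines stream keys by id)
        for rec in ind.itertuples(index=False):
            self._add_individual(int(rec.species), int(rec.guild),
                                 float(rec.x), float(rec.y),
                                 key=(int(rec.id),), iid=int(rec.id),
                                 host_iid=int(rec.host_id), t=self.t0,
                                 log_birth=False)
        # resolve host references into row indices, apply virulence
        rows = np.flatnonzero(self.alive[:self.n] & (self.guild[:self.n] == GUILD_PARASITE))
        id2row = {int(self.iid[r]): r for r in range(self.n)}
        for r in rows:
            h = id2row.get(int(self.host[r]), -1)
            if h < 0:
                raise ValueError("parasite host missing after exclusion; "
                                 "remove the parasite together with its host")
            self.host[r] = h
            self.par[h] = r
            self.x[r] = self.x[h]
            self.y[r] = self.y[h]
            self._set_rate(h, _DEATH,
                           self.rates.death_rate[self.species[h]]
                           + self.rates.virulence, self.t0)
        self._refresh_transmission()
        self._record_abundance()

    # -- low-level helpers --------------------------------------------------

    def _grow(self):
        cap = len(self.iid)
        new = cap * 2
        for name in ("iid", "species", "guild", "x", "y", "alive", "host",
                     "par", "rc", "sig", "cnt", "birth_idx", "alive_cons",
                     "rc2"):
            arr = getattr(self, name)
            grown = np.zeros(new, dtype=arr.dtype)
            if name in ("host", "par"):
                grown[:] = -1
            grown[:cap] = arr
            setattr(self, name, grown)
        for name in ("rate", "P", "T", "tlast"):
            arr = getattr(self, name)
            grown = np.zeros((new, 3), dtype=arr.dtype)
            grown[:cap] = arr
            setattr(self, name, grown)
        tf = np.full((new, 3), np.inf)
        tf[:cap] = self.tfire
        self.tfire = tf
        ubt = np.zeros((self.usable_by_type.shape[0], new), dtype=bool)
        ubt[:, :cap] = self.usable_by_type
        self.usable_by_type = ubt
        self.rngs.extend([None] * cap)
        self.keys.extend([None] * cap)

    def _rng_for(self, key: tuple) -> np.random.Generator:
        return np.random.default_rng([self.seed, 0xD1CE, *key])

    def _set_rate(self, row: int, col: int, new: float, t: float):
        self.T[row, col] += self.rate[row, col] * (t - self.tlast[row, col])
        self.tlast[row, col] = t
        self.rate[row, col] = new
        self.tfire[row, col] = (
            t + (self.P[row, col] - self.T[row, col]) / new if new > 0 else np.inf
        )

    def _set_rates_vec(self, rows: np.ndarray, col: int, new: np.ndarray, t: float):
        if len(rows) == 0:
            return
        self.T[rows, col] += self.rate[rows, col] * (t - self.tlast[rows, col])
        self.tlast[rows, col] = t
        self.rate[rows, col] = new
        tf = t + (self.P[rows, col] - self.T[rows, col]) / np.maximum(new, 1e-300)
        self.tfire[rows, col] = np.where(new > 0, tf, np.inf)

    def _fire(self, row: int, col: int, t: float):
        """Advance the internal clock of a channel that just fired."""
        self.T[row, col] = self.P[row, col]
        self.tlast[row, col] = t
        self.P[row, col] += self.rngs[row].standard_exponential()
        r = self.rate[row, col]
        self.tfire[row, col] = (
            t + (self.P[row, col] - self.T[row, col]) / r if r > 0 else np.inf
        )

    def _log(self, t, kind, actor, obj=-1, x=np.nan, y=np.nan,
             species=-1, parent=-1):
        if self.record_log:
            self.events.append((t, kind, actor, obj, x, y, species, parent))

    def _record_abundance(self):
        n = int(np.count_nonzero(self.alive[:self.n]
                                 & (self.guild[:self.n] == GUILD_CONSUMER)))
        self.abundance.append((self.t, n))

    # -- state-dependent rates ----------------------------------------------

    def _usable_in_range(self, row: int) -> np.ndarray:
        """Indices of active particles consumable by the consumer at ``row``."""
        return _idx_in_range(self.x[row], self.y[row], self.px, self.py,
                             self.pactive,
                             self.ok_by_species[self.species[row]],
                             self.rc2[row])

    def _refresh_consumption(self, row: int, t: float):
        self.cnt[row] = _count_in_range(
            self.x[row], self.y[row], self.px, self.py, self.pactive,
            self.ok_by_species[self.species[row]], self.rc2[row])
        self._set_rate(row, _ACT, self.rates.contact_rate * self.cnt[row], t)

    def _particle_neighbours(self, k: int) -> np.ndarray:
        """Rows of live consumers that can use and reach particle ``k``."""
        n = self.n
        return _idx_in_range_r(self.px[k], self.py[k], self.x[:n], self.y[:n],
                               self.alive_cons[:n],
                               self.usable_by_type[self.ptype[k], :n],
                               self.rc2[:n])

    def _particle_count_change(self, k: int, delta: int, t: float):
        rows = self._particle_neighbours(k)
        if len(rows) == 0:
            return
        self.cnt[rows] += delta
        self._set_rates_vec(rows, _ACT,
                            self.rates.contact_rate * self.cnt[rows], t)

    def _invalidate_membership(self):
        self._prows = None

    def _refresh_transmission(self, t: float | None = None):
        """Recompute susceptible-in-range counts for every live parasite,
        updating only the channels whose rate actually changed."""
        if not self.rates.has_parasites:
            return
        t = self.t if t is None else t
        n = self.n
        if getattr(self, "_prows", None) is None:
            self._prows = np.flatnonzero(
                self.alive[:n] & (self.guild[:n] == GUILD_PARASITE))
            self._crows = np.flatnonzero(
                self.alive[:n] & (self.guild[:n] == GUILD_CONSUMER)
                & (self.par[:n] == -1))
        prows, crows = self._prows, self._crows
        if len(prows) == 0:
            return
        if len(crows) == 0:
            counts = np.zeros(len(prows))
        else:
            hosts = self.host[prows]
            counts = _sus_counts(self.x[hosts], self.y[hosts],
                                 self.species[prows],
                                 self.x[crows], self.y[crows],
                                 self.species[crows],
                                 self.rates.host_range,
                                 self.rates.transmission_radius ** 2)
        new = self.rates.transmission_rate * counts
        changed = new != self.rate[prows, _ACT]
        if changed.any():
            self._set_rates_vec(prows[changed], _ACT, new[changed], t)

    # -- individuals ---------------------------------------------------------

    def _add_individual(self, species: int, guild: int, x: float, y: float,
                        key: tuple, iid: int, host_iid: int, t: float,
                        parent_iid: int = -1, log_birth: bool = True):
        if self.n == len(self.iid):
            self._grow()
        row = self.n
        self.n += 1
        self.iid[row] = iid
        self.species[row] = species
        self.guild[row] = guild
        self.x[row] = x
        self.y[row] = y
        self.alive[row] = True
        self.host[row] = host_iid  # temporarily an id; resolved by caller
        self.par[row] = -1
        self.keys[row] = key
        self.rngs[row] = self._rng_for(key)
        self.birth_idx[row] = 0
        self._invalidate_membership()
        rng = self.rngs[row]
        # initial internal firing times, drawn in fixed channel order
        self.P[row, :] = rng.standard_exponential(3)
        self.T[row, :] = 0.0
        self.tlast[row, :] = t
        if guild == GUILD_CONSUMER:
            self.rc[row] = self.rates.consumption_radius[species]
            self.rc2[row] = self.rc[row] ** 2
            self.sig[row] = self.rates.sigma[species]
            self.alive_cons[row] = True
            self.usable_by_type[:, row] = self.usable[species]
            self._set_rate(row, _MOVE, self.rates.move_rate[species], t)
            self._set_rate(row, _DEATH, self.rates.death_rate[species], t)
            self._refresh_consumption(row, t)
        else:
            self._set_rate(row, _MOVE, 0.0, t)
            self._set_rate(row, _DEATH, self.rates.parasite_death[species], t)
            self._set_rate(row, _ACT, 0.0, t)  # transmission set by refresh
        if log_birth:
            self._log(t, "birth", iid, x=x, y=y, species=species,
                      parent=parent_iid)
        return row

    def _kill(self, row: int, t: float):
        self.alive[row] = False
        self.alive_cons[row] = False
        self._invalidate_membership()
        self.rate[row, :] = 0.0
        self.tfire[row, :] = np.inf
        self._log(t, "death", int(self.iid[row]), x=self.x[row], y=self.y[row],
                  species=int(self.species[row]))

    # -- event handlers ------------------------------------------------------

    def _do_move(self, row: int, t: float):
        rng = self.rngs[row]
        dx, dy = rng.normal(0.0, self.sig[row], size=2)
        self.x[row] = wrap(self.x[row] + dx)
        self.y[row] = wrap(self.y[row] + dy)
        self._log(t, "move", int(self.iid[row]), x=self.x[row], y=self.y[row],
                  species=int(self.species[row]))
        q = self.par[row]
        if q >= 0:  # parasite rides along
            self.x[q] = self.x[row]
            self.y[q] = self.y[row]
        self._refresh_consumption(row, t)
        self._refresh_transmission(t)

    def _do_death(self, row: int, t: float):
        if self.guild[row] == GUILD_CONSUMER:
            q = self.par[row]
            self._kill(row, t)
            if q >= 0:  # host death kills its parasite
                self._kill(q, t)
            self._record_abundance()
        else:
            h = self.host[row]
            self.par[h] = -1
            self._kill(row, t)
            self._set_rate(h, _DEATH,
                           self.rates.death_rate[self.species[h]], t)
        self._refresh_transmission(t)

    def _do_consume(self, row: int, t: float):
        cand = self._usable_in_range(row)
        if len(cand) == 0:  # guarded by rate bookkeeping; defensive only
            self._refresh_consumption(row, t)
            return
        rng = self.rngs[row]
        k = int(cand[rng.integers(len(cand))])
        self.pactive[k] = False
        self.pconsumed_by[k] = self.iid[row]
        self.pconsumed_at[k] = t
        self._log(t, "consume", int(self.iid[row]), obj=int(self.pid[k]),
                  x=self.px[k], y=self.py[k], species=int(self.species[row]))
        self._particle_count_change(k, -1, t)
        self._refresh_consumption(row, t)
        if rng.random() < self.rates.birth_prob[self.species[row]]:
            bx, by = rng.normal(0.0, self.sig[row], size=2)
            child_key = self.keys[row] + (int(self.birth_idx[row]),)
            self.birth_idx[row] += 1
            child_id = self.next_id
            self.next_id += 1
            self._add_individual(int(self.species[row]), GUILD_CONSUMER,
                                 float(wrap(self.x[row] + bx)),
                                 float(wrap(self.y[row] + by)),
                                 key=child_key, iid=child_id, host_iid=-1,
                                 t=t, parent_iid=int(self.iid[row]))
            self._record_abundance()
            self._refresh_transmission(t)

    def _do_transmit(self, row: int, t: float):
        n = self.n
        h = self.host[row]
        d2 = _tdist2(self.x[h], self.y[h], self.x[:n], self.y[:n])
        m = (self.alive[:n] & (self.guild[:n] == GUILD_CONSUMER)
             & (self.par[:n] == -1)
             & self.rates.host_range[self.species[row]][self.species[:n]]
             & (d2 <= self.rates.transmission_radius ** 2))
        cand = np.flatnonzero(m)
        if len(cand) == 0:  # stale rate; resync
            self._refresh_transmission(t)
            return
        rng = self.rngs[row]
        j = int(cand[rng.integers(len(cand))])
        child_key = self.keys[row] + (int(self.birth_idx[row]),)
        self.birth_idx[row] += 1
        child_id = self.next_id
        self.next_id += 1
        self._log(t, "infect", int(self.iid[row]), obj=int(self.iid[j]),
                  x=self.x[j], y=self.y[j], species=int(self.species[row]))
        q = self._add_individual(int(self.species[row]), GUILD_PARASITE,
                                 float(self.x[j]), float(self.y[j]),
                                 key=child_key, iid=child_id,
                                 host_iid=-1, t=t,
                                 parent_iid=int(self.iid[row]))
        self.host[q] = j
        self.par[j] = q
        self._set_rate(j, _DEATH,
                       self.rates.death_rate[self.species[j]]
                       + self.rates.virulence, t)
        self._refresh_transmission(t)

    def _activate_particle(self, k: int, t: float):
        self.pactive[k] = True
        heapq.heappush(self.expiry_heap, (self.pexpire[k], k))
        self._particle_count_change(k, +1, t)

    def _expire_particle(self, k: int, t: float):
        if self.pactive[k]:
            self.pactive[k] = False
            self._particle_count_change(k, -1, t)

    # -- main loop ------------------------------------------------------------

    def run(self):
        t_end = self.t0 + self.horizon
        n3 = None
        while True:
            nalive = int(np.count_nonzero(self.alive[:self.n]))
            if nalive == 0:
                self.extinct = True
                break
            view = self.tfire[:self.n]
            flat = int(np.argmin(view))
            row, col = divmod(flat, 3)
            t_ch = view[row, col]
            t_prod = (self.pcreate[self.prod_order[self.prod_ptr]]
                      if self.prod_ptr < len(self.prod_order) else np.inf)
            t_exp = self.expiry_heap[0][0] if self.expiry_heap else np.inf
            t_next = min(t_ch, t_prod, t_exp)
            if t_next > t_end or not np.isfinite(t_next):
                break
            self.t = t_next
            if t_exp <= t_prod and t_exp <= t_ch:
                _, k = heapq.heappop(self.expiry_heap)
                self._expire_particle(k, t_next)
            elif t_prod <= t_ch:
                k = int(self.prod_order[self.prod_ptr])
                self.prod_ptr += 1
                self._activate_particle(k, t_next)
            else:
                self._fire(row, col, t_next)
                if col == _MOVE:
                    self._do_move(row, t_next)
                elif col == _DEATH:
                    self._do_death(row, t_next)
                elif self.guild[row] == GUILD_CONSUMER:
                    self._do_consume(row, t_next)
                else:
                    self._do_transmit(row, t_next)
        if not self.extinct:
            self.t = t_end
        return self

    # -- outputs --------------------------------------------------------------

    def state(self) -> Snapshot:
        n = self.n
        live = np.flatnonzero(self.alive[:n])
        host_ids = np.where(self.host[live] >= 0,
                            self.iid[np.maximum(self.host[live], 0)], -1)
        ind = pd.DataFrame({
            "id": self.iid[live],
            "species": self.species[live],
            "guild": self.guild[live],
            "x": self.x[live],
            "y": self.y[live],
            "host_id": host_ids,
            "born_at": 0.0,
        })
        act = np.flatnonzero(self.pactive)
        res = pd.DataFrame({
            "id": self.pid[act],
            "rtype": self.ptype[act],
            "x": self.px[act],
            "y": self.py[act],
            "created_at": self.pcreate[act],
        })
        return Snapshot(time=float(self.t), individuals=ind, resources=res)

    def log(self) -> EventLog:
        ev = pd.DataFrame(self.events, columns=EVENT_COLUMNS)
        touched = self.pcreate <= self.t  # particles that existed during run
        particles = pd.DataFrame({
            "id": self.pid[touched],
            "rtype": self.ptype[touched],
            "x": self.px[touched],
            "y": self.py[touched],
            "created_at": self.pcreate[touched],
            "consumed_by": self.pconsumed_by[touched],
            "consumed_at": self.pconsumed_at[touched],
        })
        init = Snapshot(time=self.t0,
                        individuals=self._initial_individuals,
                        resources=self._initial_resources)
        return EventLog(t0=self.t0, horizon=self.horizon, events=ev,
                        particles=particles, initial=init,
                        extinct=self.extinct)


def _build_engine(config, snapshot, horizon, seed, exclude=(),
                  production=None):
    eng = _Engine(config, snapshot, horizon, seed, exclude=exclude,
                  production=production)
    # keep a pristine copy of the initial condition for the log
    ind = snapshot.individuals
    keep = ~ind.id.isin(set(int(i) for i in exclude))
    eng._initial_individuals = ind[keep].reset_index(drop=True)
    eng._initial_resources = snapshot.resources.copy()
    return eng


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def run(config: SimConfig, initial: Snapshot, horizon: float, seed: int,
        exclude: Iterable[int] = ()) -> tuple:
    """Simulate ``horizon`` time units from ``initial``; exact given ``seed``.

    Returns ``(final_state, event_log)``.  If every individual dies the run
    stops early and both the log and the returned state are flagged
    (``log.extinct``); this is reported, not raised, so that replicate sweeps
    can continue.
    """
    eng = _build_engine(config, initial, horizon, seed, exclude=exclude).run()
    if eng.extinct:
        warnings.warn("population went extinct before the horizon",
                      RuntimeWarning, stacklevel=2)
    return eng.state(), eng.log()


def initial_state(config: SimConfig, n_per_species: int, seed: int,
                  parasites_per_species: int = 0) -> Snapshot:
    """Dispersed starting state used to begin burn-in.

    Consumers are placed at production locations of a resource type their
    species uses (so patchy landscapes start populated inside patches), and
    the resource pool is pre-seeded with the stream from one particle
    lifetime so that consumption can start immediately.
    """
    rng = np.random.default_rng([seed, 0x5EED])
    rows = []
    next_id = 0
    for s in range(config.niche.n_species):
        types = np.flatnonzero(config.niche.usage[s])
        for _ in range(n_per_species):
            rtype = int(types[rng.integers(len(types))])
            x, y = config.landscape.sample_point(rtype, rng)
            rows.append((next_id, s, GUILD_CONSUMER, x, y, -1, 0.0))
            next_id += 1
    ind = pd.DataFrame(rows, columns=INDIVIDUAL_COLUMNS)
    if parasites_per_species and config.rates.has_parasites:
        hr = config.rates.host_range
        prows = []
        free = ind[ind.guild == GUILD_CONSUMER].copy()
        for q in range(config.rates.n_parasite_species):
            hosts = free[free.species.isin(np.flatnonzero(hr[q]))]
            take = hosts.sample(n=min(parasites_per_species, len(hosts)),
                                random_state=int(rng.integers(2**31)))
            for h in take.itertuples(index=False):
                prows.append((next_id, q, GUILD_PARASITE, h.x, h.y, h.id, 0.0))
                next_id += 1
                free = free[free.id != h.id]
        ind = pd.concat([ind, pd.DataFrame(prows, columns=INDIVIDUAL_COLUMNS)],
                        ignore_index=True)
    tau = config.rates.resource_lifetime
    res = sample_resource_events(config.landscape, tau, seed,
                                 t0=-tau)
    res = res[RESOURCE_COLUMNS]
    return Snapshot(time=0.0, individuals=ind, resources=res)


def _abundance_slope_t(series: list, t_lo: float, t_hi: float) -> float:
    """|t|-statistic of the OLS abundance trend over [t_lo, t_hi]."""
    arr = np.asarray(series, dtype=float)
    sel = (arr[:, 0] >= t_lo) & (arr[:, 0] <= t_hi)
    pts = arr[sel]
    if len(pts) < 24:
        return np.inf
    # regress block means: abundance is strongly autocorrelated, so raw
    # event-level points would wildly overstate the significance of a trend
    n_blocks = 12
    edges = np.linspace(t_lo, t_hi, n_blocks + 1)
    which = np.clip(np.digitize(pts[:, 0], edges) - 1, 0, n_blocks - 1)
    t = np.array([(edges[b] + edges[b + 1]) / 2 for b in range(n_blocks)])
    n = np.array([pts[which == b, 1].mean() if (which == b).any() else np.nan
                  for b in range(n_blocks)])
    ok = ~np.isnan(n)
    if ok.sum() < 6 or np.ptp(n[ok]) == 0:
        return 0.0 if ok.sum() and np.ptp(n[ok]) == 0 else np.inf
    fit = stats.linregress(t[ok], n[ok])
    if fit.stderr == 0:
        return 0.0
    return abs(fit.slope / fit.stderr)


def run_to_stationarity(config: SimConfig, seed: int,
                        n_per_species: int = 10,
                        parasites_per_species: int = 4,
                        t_burn: float = 30.0, max_time: float = 90.0,
                        min_species: int = 2) -> Snapshot:
    """Burn in until the total-abundance trend is flat, then freeze a snapshot.

    The diagnostic fits an OLS line to the consumer abundance series over the
    most recent half of the elapsed burn-in and passes when the slope is not
    significantly different from zero (|t| < 2 on ~100 thinned support
    points).  The burn-in is extended in half-``t_burn`` steps until the
    diagnostic passes or ``max_time`` is exhausted (:class:`StationarityError`).

    The returned snapshot is relabelled: individuals get ids ``0..N-1``
    (consumers first) and its clock is reset to zero, so it can serve as the
    common, seed-independent initial condition of all replicate runs.
    """
    state = initial_state(config, n_per_species, seed,
                          parasites_per_species if config.rates.has_parasites else 0)
    series: list = []
    elapsed = 0.0
    segment = float(t_burn)
    chunk = 0
    while True:
        eng = _build_engine(config, state, segment, int(seed) + 7919 * chunk).run()
        chunk += 1
        if eng.extinct:
            raise ExtinctionError("metacommunity went extinct during burn-in")
        series.extend(eng.abundance)
        state = eng.state()
        elapsed = state.time
        tstat = _abundance_slope_t(series, elapsed / 2.0, elapsed)
        if elapsed >= t_burn and tstat < 2.0:
            break
        if elapsed >= max_time:
            raise StationarityError(
                f"abundance trend still significant after t={elapsed:.1f} "
                f"(|t|={tstat:.2f})")
        segment = t_burn / 2.0

    ind = state.individuals
    n_sp = ind.loc[ind.guild == GUILD_CONSUMER, "species"].nunique()
    if n_sp < min_species:
        raise ExtinctionError(
            f"only {n_sp} consumer species persist at stationarity")

    # relabel to compact ids, consumers first, and reset the clock
    ind = ind.sort_values(["guild", "id"]).reset_index(drop=True)
    remap = {int(old): new for new, old in enumerate(ind.id)}
    ind["id"] = np.arange(len(ind))
    ind["host_id"] = [remap.get(int(h), -1) for h in ind.host_id]
    ind["born_at"] = 0.0
    res = state.resources.sort_values("id").reset_index(drop=True)
    res["id"] = np.arange(len(res))
    res["created_at"] = res.created_at - state.time
    return Snapshot(time=0.0, individuals=ind, resources=res)


def run_replicate(config: SimConfig, snapshot: Snapshot, horizon: float,
                  seed: int) -> EventLog:
    """One replicate run from the fixed snapshot; logs keep snapshot ids."""
    eng = _build_engine(config, snapshot, horizon, seed).run()
    return eng.log()


def removal_replicate(config: SimConfig, snapshot: Snapshot, focal: int,
                      horizon: float, seed: int) -> tuple:
    """Paired control / treatment runs sharing the same random streams.

    The treatment removes the focal individual before time zero; if the focal
    is an infected consumer its parasite is removed with it (parasites are
    not free-living).  Returns ``(control_log, treatment_log)``.
    """
    ind = snapshot.individuals
    if int(focal) not in set(int(i) for i in ind.id):
        raise KeyError(f"focal individual {focal} not in snapshot")
    exclude = {int(focal)}
    riders = ind.loc[(ind.guild == GUILD_PARASITE) & (ind.host_id == focal), "id"]
    exclude.update(int(i) for i in riders)
    control = run_replicate(config, snapshot, horizon, seed)
    treat = _build_engine(config, snapshot, horizon, seed,
                          exclude=exclude).run().log()
    return control, treat
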