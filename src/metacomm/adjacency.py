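"""Estimating the metacommunity adjacency matrix P = (p_ij).

Three definitions of the pairwise link ``p_ij`` between individuals are
implemented, all estimated from replicate simulations started at a common
snapshot:

``space``
    Bhattacharyya overlap of the two individuals' utilisation distributions
    ``C_i(x, y)``, discretised on a G x G grid:
    ``p_ij = sum_cells sqrt(C_i * C_j)`` (1 = identical space use,
    0 = disjoint).  Symmetric with unit diagonal.
``interaction``
    the proportion of replicate runs in which the pair interacted at least
    once.  Two consumers interact when one consumes a particle that at that
    moment lies within the consumption radius of the other and is of a type
    both species use; a parasite interacts with the host it infects; two
    parasites interact when one infects a host that the other could also
    have infected at that moment.  Symmetric, in [0, 1].
``influence``
    the mean treatment-minus-control difference in the number of offspring
    produced by individual j when the focal individual i is removed before
    time zero.  Signed and, in general, asymmetric (commensalism: removing
    the beneficiary leaves its partner unaffected, removing the partner
    hurts the beneficiary).

Adjacencies are estimated among snapshot individuals only; events by
replicate-born descendants are credited to their snapshot ancestor.
:func:`run_until_converged` grows the replicate set in batches until the
estimate stabilises in relative Frobenius norm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .landscape import NicheMatrix, torus_distance
from .simulator import (
    EventLog,
    GUILD_CONSUMER,
    GUILD_PARASITE,
    SimConfig,
    Snapshot,
    ancestor_map,
    ancestral_offspring_counts,
    derive_seed,
    run_replicate,
    _build_engine,
    _sample_production,
)

DEFINITIONS = ("space", "interaction", "influence")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpaceUseField:
    """Discretised utilisation distribution of one individual."""

    individual: int
    grid: int
    weights: np.ndarray  # (G, G), non-negative, sums to 1

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (self.grid, self.grid):
            raise ValueError("weights must be a G x G raster")
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be a probability distribution")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.weights).to_csv(path, index=False, header=False)


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Individuals x individuals link weights under one definition."""

    definition: str
    ids: tuple
    weights: np.ndarray
    symmetric: bool
    signed: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "ids", tuple(int(i) for i in self.ids))
        if w.shape != (len(self.ids), len(self.ids)):
            raise ValueError("weight matrix does not match id list")
        if self.definition not in DEFINITIONS:
            raise ValueError(f"unknown definition {self.definition!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def working_weights(self) -> np.ndarray:
        """Non-negative weights with zero diagonal, as used for partitioning.

        Signed (influence) matrices contribute their magnitudes; the sign is
        retained in ``weights`` for reporting.
        """
        w = np.abs(self.weights) if self.signed else self.weights.copy()
        np.fill_diagonal(w, 0.0)
        return w

    def subset(self, ids: Sequence[int]) -> "AdjacencyMatrix":
        pos = {i: k for k, i in enumerate(self.ids)}
        idx = np.array([pos[int(i)] for i in ids], dtype=int)
        return AdjacencyMatrix(self.definition, tuple(int(i) for i in ids),
                               self.weights[np.ix_(idx, idx)],
                               self.symmetric, self.signed, dict(self.provenance))

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, path, sidecar: bool = True) -> None:
        df = pd.DataFrame(self.weights, index=list(self.ids),
                          columns=list(self.ids))
        df.to_csv(path)
        if sidecar:
            meta = {"definition": self.definition,
                    "symmetric": self.symmetric, "signed": self.signed,
                    **self.provenance}
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, default=str)

    @classmethod
    def from_csv(cls, path, definition: str = "space",
                 signed: bool = False) -> "AdjacencyMatrix":
        df = pd.read_csv(path, index_col=0)
        w = df.to_numpy(dtype=float)
        return cls(definition, tuple(int(i) for i in df.columns), w,
                   symmetric=bool(np.allclose(w, w.T)), signed=signed)

    def to_edgelist(self, path) -> None:
        rows = []
        for a in range(self.n):
            for b in range(self.n):
                if a != b and self.weights[a, b] != 0:
                    rows.append((self.ids[a], self.ids[b], self.weights[a, b]))
        pd.DataFrame(rows, columns=["i", "j", "weight"]).to_csv(
            path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# space use
# ---------------------------------------------------------------------------

def _cell_of(x: float, y: float, grid: int) -> int:
    return (int(x * grid) % grid) * grid + (int(y * grid) % grid)


def _sojourn_pass(log: EventLog, grid: int) -> tuple:
    """One pass over a log: per-individual cell-sojourn times.

    Returns ``(times, alive)`` dicts keyed by individual id; ``times[i]`` is a
    flat ``G*G`` array of residence times accumulated from the
    piecewise-constant location process, ``alive[i]`` the total time alive.
    Covers snapshot individuals and any individual born during the run.
    Parasites have no move events of their own; their location follows the
    host they ride, so host moves are accounted to the rider as well.
    """
    times: dict = {}
    alive: dict = {}
    pos: dict = {}
    t_last: dict = {}
    host_of: dict = {}   # parasite -> host
    rider: dict = {}     # host -> parasite
    pending_host: dict = {}

    def _init(i, x, y, t):
        times[i] = np.zeros(grid * grid)
        alive[i] = 0.0
        pos[i] = (float(x), float(y))
        t_last[i] = float(t)

    def _account(i, t):
        px, py = pos[i]
        dt = float(t) - t_last[i]
        times[i][_cell_of(px, py, grid)] += dt
        alive[i] += dt
        t_last[i] = float(t)

    for rec in log.initial.individuals.itertuples(index=False):
        i = int(rec.id)
        _init(i, rec.x, rec.y, log.t0)
        if int(rec.guild) == GUILD_PARASITE:
            host_of[i] = int(rec.host_id)
            rider[int(rec.host_id)] = i
    ev = log.events
    sel = ev.kind.isin(("move", "death", "birth", "infect")).to_numpy()
    for t, kind, actor, obj, x, y, parent in zip(
            ev.time.to_numpy()[sel], ev.kind.to_numpy()[sel],
            ev.actor.to_numpy()[sel], ev.object.to_numpy()[sel],
            ev.x.to_numpy()[sel], ev.y.to_numpy()[sel],
            ev.parent.to_numpy()[sel]):
        i = int(actor)
        if kind == "infect":
            pending_host[i] = int(obj)
            continue
        if kind == "birth":
            _init(i, x, y, t)
            p = int(parent)
            if p in pending_host:  # new parasite riding the infected host
                h = pending_host.pop(p)
                host_of[i] = h
                rider[h] = i
            continue
        if i not in pos:
            continue
        _account(i, t)
        if kind == "move":
            q = rider.get(i)
            if q is not None and q in pos:
                _account(q, t)
                pos[q] = (float(x), float(y))
            pos[i] = (float(x), float(y))
        else:  # death
            del pos[i]
            if i in host_of:
                rider.pop(host_of.pop(i), None)
    t_end = log.t0 + log.horizon
    for i in list(pos):
        _account(i, t_end)
    return times, alive


def estimate_space_use(logs: EventLog | Sequence[EventLog], individual: int,
                       grid: int = 32) -> SpaceUseField:
    """Utilisation distribution of one individual, pooled over replicates.

    Cell weight = time resident in the cell / total time alive, accumulated
    exactly from sojourn intervals between consecutive move events.
    """
    if isinstance(logs, EventLog):
        logs = [logs]
    acc = np.zeros(grid * grid)
    tot = 0.0
    for log in logs:
        times, alive = _sojourn_pass(log, grid)
        if int(individual) in times:
            acc += times[int(individual)]
            tot += alive[int(individual)]
    if tot <= 0:
        raise ValueError(f"individual {individual} has zero alive time")
    return SpaceUseField(int(individual), grid, (acc / tot).reshape(grid, grid))


def bhattacharyya_overlap(c_i: SpaceUseField, c_j: SpaceUseField) -> float:
    """Bhattacharyya coefficient between two discretised utilisation fields."""
    if c_i.grid != c_j.grid:
        raise ValueError("space-use fields live on different grids")
    v = float(np.sqrt(c_i.weights * c_j.weights).sum())
    return min(max(v, 0.0), 1.0)


def space_use_adjacency(logs: Sequence[EventLog], ids: Sequence[int],
                        grid: int = 32,
                        provenance: dict | None = None) -> AdjacencyMatrix:
    """Pairwise Bhattacharyya overlap among ``ids``, pooled over ``logs``."""
    acc = np.zeros((len(ids), grid * grid))
    for log in logs:
        times, _ = _sojourn_pass(log, grid)
        for k, i in enumerate(ids):
            if int(i) in times:
                acc[k] += times[int(i)]
    tot = acc.sum(axis=1, keepdims=True)
    if (tot <= 0).any():
        bad = [ids[k] for k in np.flatnonzero(tot[:, 0] <= 0)]
        raise ValueError(f"zero alive time for individuals {bad}")
    s = np.sqrt(acc / tot)
    w = np.clip(s @ s.T, 0.0, 1.0)
    np.fill_diagonal(w, 1.0)
    return AdjacencyMatrix("space", tuple(ids), w, symmetric=True,
                           provenance=provenance or {})


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------

def detect_interactions(log: EventLog, niche: NicheMatrix,
                        host_range: np.ndarray | None = None,
                        r_c: float | np.ndarray = 0.04,
                        r_t: float = 0.08) -> set:
    """Unordered pairs of individuals that interacted during one run.

    Pairs are returned with raw log ids (including replicate-born
    individuals); see :func:`interaction_pairs` for the snapshot-ancestor
    version used to build adjacency matrices.  All distances are toroidal and
    evaluated at the event time.
    """
    r_c = np.asarray(r_c, dtype=float)
    if r_c.ndim == 0:
        r_c = np.full(niche.n_species, float(r_c))
    rtype_of = dict(zip(log.particles.id.astype(int),
                        log.particles.rtype.astype(int)))
    # replayed state ------------------------------------------------------
    pos: dict = {}
    species: dict = {}
    host_of: dict = {}   # parasite id -> host id
    psp: dict = {}       # parasite id -> parasite species
    for rec in log.initial.individuals.itertuples(index=False):
        i = int(rec.id)
        if int(rec.guild) == GUILD_CONSUMER:
            pos[i] = (float(rec.x), float(rec.y))
            species[i] = int(rec.species)
        else:
            host_of[i] = int(rec.host_id)
            psp[i] = int(rec.species)
    pairs: set = set()
    pending_host: dict = {}  # infecting parasite -> host, for the birth that follows
    for rec in log.events.itertuples(index=False):
        kind = rec.kind
        i = int(rec.actor)
        if kind == "move":
            pos[i] = (float(rec.x), float(rec.y))
        elif kind == "death":
            pos.pop(i, None)
            host_of.pop(i, None)
        elif kind == "birth":
            parent = int(rec.parent)
            if parent in pending_host:  # parasite born through infection
                host_of[i] = pending_host.pop(parent)
                psp[i] = int(rec.species)
            elif parent in host_of or parent in psp:
                # defensive: parasite birth without a pending infect record
                psp[i] = int(rec.species)
            else:
                pos[i] = (float(rec.x), float(rec.y))
                species[i] = int(rec.species)
        elif kind == "consume":
            rtype = rtype_of[int(rec.object)]
            px, py = float(rec.x), float(rec.y)
            for j, (jx, jy) in pos.items():
                if j == i:
                    continue
                sj = species[j]
                if niche.usage[sj, rtype] and \
                        torus_distance(px, py, jx, jy) <= r_c[sj]:
                    pairs.add(tuple(sorted((i, j))))
        elif kind == "infect":
            h = int(rec.object)
            pairs.add(tuple(sorted((i, h))))
            pending_host[i] = h
            if host_range is not None:
                hx, hy = float(rec.x), float(rec.y)
                h_sp = species[h]
                for q, qhost in host_of.items():
                    if q == i or qhost not in pos:
                        continue
                    if not host_range[psp[q], h_sp]:
                        continue
                    qx, qy = pos[qhost]
                    if torus_distance(hx, hy, qx, qy) <= r_t:
                        pairs.add(tuple(sorted((i, q))))
    return pairs


def interaction_pairs(log: EventLog, config: SimConfig) -> set:
    """Interacting pairs mapped to snapshot ancestors.

    Pairs that collapse onto a single ancestor (e.g., a parent interacting
    with its own offspring) are dropped, since the adjacency diagonal is
    excluded from partitioning.
    """
    raw = detect_interactions(log, config.niche, config.rates.host_range,
                              r_c=config.rates.consumption_radius,
                              r_t=config.rates.transmission_radius)
    roots = ancestor_map(log)
    out = set()
    for a, b in raw:
        ra, rb = roots.get(a, a), roots.get(b, b)
        if ra != rb:
            out.add(tuple(sorted((ra, rb))))
    return out


def interaction_adjacency(pair_sets: Sequence[set], ids: Sequence[int],
                          provenance: dict | None = None) -> AdjacencyMatrix:
    """p_ij = proportion of replicates in which the pair interacted."""
    if len(pair_sets) < 1:
        raise ValueError("need at least one replicate pair-set")
    pos = {int(i): k for k, i in enumerate(ids)}
    w = np.zeros((len(ids), len(ids)))
    for pairs in pair_sets:
        for a, b in pairs:
            if a in pos and b in pos:
                w[pos[a], pos[b]] += 1
                w[pos[b], pos[a]] += 1
    w /= len(pair_sets)
    return AdjacencyMatrix("interaction", tuple(ids), w, symmetric=True,
                           provenance=provenance or {})


# ---------------------------------------------------------------------------
# influence (removal experiments)
# ---------------------------------------------------------------------------

def influence_adjacency(config: SimConfig, snapshot: Snapshot, horizon: float,
                        n_replicates: int, seed: int,
                        provenance: dict | None = None) -> AdjacencyMatrix:
    """Signed influence matrix from paired removal experiments.

    For every replicate seed one control run is simulated, then one treatment
    run per focal individual with that individual (and any parasite it
    carries) deleted before time zero, sharing the control's random streams.
    ``p_ij`` is the mean over replicates of the treatment-minus-control
    difference in offspring credited to j's lineage.
    """
    ids = [int(i) for i in snapshot.ids]
    ind = snapshot.individuals
    w = np.zeros((len(ids), len(ids)))
    for rep in range(n_replicates):
        s = derive_seed(seed, 0x1F, rep)
        prod = _sample_production(config, snapshot, horizon, s)
        control = _build_engine(config, snapshot, horizon, s,
                                production=prod).run().log()
        o_ctrl = ancestral_offspring_counts(control, ids)
        for k, focal in enumerate(ids):
            exclude = {focal}
            riders = ind.loc[(ind.guild == GUILD_PARASITE)
                             & (ind.host_id == focal), "id"]
            exclude.update(int(r) for r in riders)
            treat = _build_engine(config, snapshot, horizon, s,
                                  exclude=exclude, production=prod
                                  ).run().log()
            o_trt = ancestral_offspring_counts(treat, ids)
            diff = o_trt - o_ctrl
            diff[k] = 0.0  # focal absent from treatment; diagonal excluded
            w[k] += diff
    w /= n_replicates
    prov = {"replicates": n_replicates, "horizon": horizon, **(provenance or {})}
    return AdjacencyMatrix("influence", tuple(ids), w,
                           symmetric=False, signed=True, provenance=prov)


# ---------------------------------------------------------------------------
# incremental estimators + convergence controller
# ---------------------------------------------------------------------------

class SpaceUseEstimator:
    """Accumulates pooled sojourn rasters over replicates."""

    definition = "space"

    def __init__(self, config: SimConfig, snapshot: Snapshot, horizon: float,
                 grid: int = 32):
        self.config, self.snapshot = config, snapshot
        self.horizon, self.grid = horizon, grid
        self.ids = [int(i) for i in snapshot.ids]
        self.acc = np.zeros((len(self.ids), grid * grid))
        self.n_replicates = 0

    def add_replicate(self, seed: int) -> None:
        log = run_replicate(self.config, self.snapshot, self.horizon, seed)
        times, _ = _sojourn_pass(log, self.grid)
        for k, i in enumerate(self.ids):
            if i in times:
                self.acc[k] += times[i]
        self.n_replicates += 1

    def matrix(self) -> np.ndarray:
        tot = self.acc.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        s = np.sqrt(self.acc / tot)
        w = np.clip(s @ s.T, 0.0, 1.0)
        np.fill_diagonal(w, 1.0)
        return w

    def to_adjacency(self, provenance: dict | None = None) -> AdjacencyMatrix:
        prov = {"replicates": self.n_replicates, "grid": self.grid,
                **(provenance or {})}
        return AdjacencyMatrix("space", tuple(self.ids), self.matrix(),
                               symmetric=True, provenance=prov)


class InteractionEstimator:
    """Accumulates per-replicate interacting pair sets."""

    definition = "interaction"

    def __init__(self, config: SimConfig, snapshot: Snapshot, horizon: float):
        self.config, self.snapshot, self.horizon = config, snapshot, horizon
        self.ids = [int(i) for i in snapshot.ids]
        self._pos = {i: k for k, i in enumerate(self.ids)}
        self.counts = np.zeros((len(self.ids), len(self.ids)))
        self.n_replicates = 0

    def add_replicate(self, seed: int) -> None:
        log = run_replicate(self.config, self.snapshot, self.horizon, seed)
        for a, b in interaction_pairs(log, self.config):
            if a in self._pos and b in self._pos:
                self.counts[self._pos[a], self._pos[b]] += 1
                self.counts[self._pos[b], self._pos[a]] += 1
        self.n_replicates += 1

    def matrix(self) -> np.ndarray:
        if self.n_replicates == 0:
            return self.counts.copy()
        return self.counts / self.n_replicates

    def to_adjacency(self, provenance: dict | None = None) -> AdjacencyMatrix:
        prov = {"replicates": self.n_replicates, **(provenance or {})}
        return AdjacencyMatrix("interaction", tuple(self.ids), self.matrix(),
                               symmetric=True, provenance=prov)


class InfluenceEstimator:
    """Accumulates paired removal sweeps (one control + one run per focal)."""

    definition = "influence"

    def __init__(self, config: SimConfig, snapshot: Snapshot, horizon: float):
        self.config, self.snapshot, self.horizon = config, snapshot, horizon
        self.ids = [int(i) for i in snapshot.ids]
        self.sums = np.zeros((len(self.ids), len(self.ids)))
        self.n_replicates = 0

    def add_replicate(self, seed: int) -> None:
        ind = self.snapshot.individuals
        prod = _sample_production(self.config, self.snapshot, self.horizon,
                                  seed)
        control = _build_engine(self.config, self.snapshot, self.horizon,
                                seed, production=prod).run().log()
        o_ctrl = ancestral_offspring_counts(control, self.ids)
        for k, focal in enumerate(self.ids):
            exclude = {focal}
            riders = ind.loc[(ind.guild == GUILD_PARASITE)
                             & (ind.host_id == focal), "id"]
            exclude.update(int(r) for r in riders)
            treat = _build_engine(self.config, self.snapshot, self.horizon,
                                  seed, exclude=exclude, production=prod
                                  ).run().log()
            diff = ancestral_offspring_counts(treat, self.ids) - o_ctrl
            diff[k] = 0.0
            self.sums[k] += diff
        self.n_replicates += 1

    def matrix(self) -> np.ndarray:
        if self.n_replicates == 0:
            return self.sums.copy()
        return self.sums / self.n_replicates

    def to_adjacency(self, provenance: dict | None = None) -> AdjacencyMatrix:
        prov = {"replicates": self.n_replicates, **(provenance or {})}
        return AdjacencyMatrix("influence", tuple(self.ids), self.matrix(),
                               symmetric=False, signed=True, provenance=prov)


@dataclass
class ConvergenceInfo:
    replicates: int
    deltas: list
    converged: bool
    tol: float


def run_until_converged(estimator, seed: int, batch: int = 50,
                        tol: float = 0.05, max_replicates: int = 1000
                        ) -> tuple:
    """Grow the replicate set until the adjacency estimate stabilises.

    After each batch the relative Frobenius change between successive
    cumulative estimates is computed; the loop stops when it falls below
    ``tol``.  Hitting ``max_replicates`` without convergence returns a
    flagged (``converged=False``) result with a warning rather than failing
    silently.  Returns ``(AdjacencyMatrix, ConvergenceInfo)``.
    """
    if batch < 1 or tol <= 0:
        raise ValueError("batch must be >= 1 and tol > 0")
    eps = 1e-12
    prev = None
    deltas: list = []
    converged = False
    while estimator.n_replicates < max_replicates:
        for _ in range(batch):
            estimator.add_replicate(derive_seed(seed, 0xC0, estimator.n_replicates))
            if estimator.n_replicates >= max_replicates:
                break
        cur = estimator.matrix()
        if prev is not None:
            delta = np.linalg.norm(cur - prev) / max(np.linalg.norm(cur), eps)
            deltas.append(float(delta))
            if delta < tol:
                converged = True
                break
        prev = cur
    if not converged:
        warnings.warn(
            f"adjacency estimate not converged after {estimator.n_replicates} "
            f"replicates (last delta {deltas[-1] if deltas else np.nan})",
            RuntimeWarning, stacklevel=2)
    info = ConvergenceInfo(estimator.n_replicates, deltas, converged, tol)
    adj = estimator.to_adjacency({"seed": seed, "tol": tol,
                                  "converged": converged})
    return adj, info
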