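"""Landscapes, resource production and consumer niches.

The simulation arena is the unit torus ``[0, 1) x [0, 1)`` (periodic in both
axes, so there are no edge effects in movement or in distance decay).  A
:class:`Landscape` describes, for each resource type, the spatial intensity of
resource-particle production (particles per unit area per unit time).  Three
landscape kinds are supported:

``homogeneous``
    every resource type is produced uniformly over the whole arena;
``heterogeneous``
    circular habitat patches differ in the *mix* of resource types they
    produce, but a low uniform background keeps every location habitable
    (the landscape is continuous);
``patchy``
    discrete habitat patches produce all resource types and the matrix
    between patches produces nothing (it is unhabitable).

Resource production is a Poisson point process in space-time: the number of
particles appearing in a region ``A`` during a window of length ``T`` is
Poisson with mean ``T * integral_A intensity``.  :func:`sample_resource_events`
realises this process exactly by drawing per-type Poisson counts, then uniform
event times and intensity-weighted locations.

Consumer species are linked to resource types through a binary
:class:`NicheMatrix`; pairs of species are classed as having *none*, *partial*
or *complete* resource-use overlap, the classification used throughout the
distance-decay diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

LandscapeKind = Literal["homogeneous", "heterogeneous", "patchy"]

#: side length of the (square, periodic) arena
DOMAIN_SIZE = 1.0


# ---------------------------------------------------------------------------
# toroidal geometry helpers (used by every other module)
# ---------------------------------------------------------------------------

def torus_delta(a, b, size: float = DOMAIN_SIZE):
    """Per-axis shortest displacement magnitude on a periodic axis."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % size
    return np.minimum(d, size - d)


def torus_distance(x1, y1, x2, y2, size: float = DOMAIN_SIZE):
    """Shortest (great-circle-free) Euclidean distance on the torus."""
    return np.hypot(torus_delta(x1, x2, size), torus_delta(y1, y2, size))


def wrap(z, size: float = DOMAIN_SIZE):
    """Wrap coordinates back into ``[0, size)``."""
    return np.mod(z, size)


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Patch:
    """Circular habitat patch with a per-resource-type production weight."""

    cx: float
    cy: float
    radius: float
    weights: tuple  # length n_types, non-negative

    @property
    def area(self) -> float:
        return float(np.pi * self.radius**2)


class ConfigurationError(ValueError):
    """Raised for landscape / scenario configurations that violate a precondition."""


@dataclass(frozen=True)
class Landscape:
    """Spatial production regime for resource particles.

    Parameters
    ----------
    kind:
        one of ``homogeneous``, ``heterogeneous``, ``patchy``.
    rates:
        per-type total production rate over the whole arena
        (particles per unit time).
    patches:
        circular patches; empty for homogeneous landscapes.
    background:
        fraction of each type's production emitted uniformly over the whole
        arena rather than from patches.  1 for homogeneous, 0 for patchy and
        a small positive value for heterogeneous landscapes (which keeps them
        habitable everywhere).
    """

    kind: LandscapeKind
    rates: tuple
    patches: tuple = ()
    background: float = 1.0

    def __post_init__(self):
        if self.kind not in ("homogeneous", "heterogeneous", "patchy"):
            raise ConfigurationError(f"unknown landscape kind: {self.kind!r}")
        if any(r < 0 for r in self.rates):
            raise ConfigurationError("production rates must be non-negative")
        if not 0.0 <= self.background <= 1.0:
            raise ConfigurationError("background fraction must lie in [0, 1]")
        for p in self.patches:
            if not (0 < p.radius < DOMAIN_SIZE / 2):
                raise ConfigurationError(
                    f"patch radius {p.radius} does not fit the periodic domain"
                )

    # -- derived quantities -------------------------------------------------

    @property
    def n_types(self) -> int:
        return len(self.rates)

    def _patch_shares(self, rtype: int) -> np.ndarray:
        """Fraction of type ``rtype``'s patch-borne production per patch."""
        w = np.array([p.weights[rtype] for p in self.patches], dtype=float)
        tot = w.sum()
        return w / tot if tot > 0 else w

    def total_rate(self, rtype: int) -> float:
        return float(self.rates[rtype])

    def intensity(self, x, y, rtype: int):
        """Production intensity (particles / area / time) at ``(x, y)``."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.full(np.broadcast(x, y).shape, self.rates[rtype] * self.background,
                      dtype=float)
        if self.patches:
            shares = self._patch_shares(rtype)
            patch_rate = self.rates[rtype] * (1.0 - self.background)
            for p, s in zip(self.patches, shares):
                inside = torus_distance(x, y, p.cx, p.cy) <= p.radius
                out = out + inside * (patch_rate * s / p.area)
        return out if out.shape else float(out)

    def sample_point(self, rtype: int, rng: np.random.Generator) -> tuple:
        """Draw a production location for one particle of type ``rtype``."""
        if rng.random() < self.background:
            return float(rng.random()), float(rng.random())
        shares = self._patch_shares(rtype)
        if shares.sum() == 0:
            # type produced nowhere in patches: fall back to background
            return float(rng.random()), float(rng.random())
        k = rng.choice(len(self.patches), p=shares)
        p = self.patches[k]
        r = p.radius * np.sqrt(rng.random())
        theta = 2 * np.pi * rng.random()
        return (float(wrap(p.cx + r * np.cos(theta))),
                float(wrap(p.cy + r * np.sin(theta))))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "rates": list(self.rates),
            "background": self.background,
            "patches": [
                {"cx": p.cx, "cy": p.cy, "radius": p.radius,
                 "weights": list(p.weights)}
                for p in self.patches
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Landscape":
        return cls(
            kind=d["kind"],
            rates=tuple(d["rates"]),
            background=d["background"],
            patches=tuple(
                Patch(p["cx"], p["cy"], p["radius"], tuple(p["weights"]))
                for p in d["patches"]
            ),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Landscape":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class LandscapeParams:
    """Tunable knobs for :func:`make_landscape`.

    ``rate_per_type`` is the arena-wide production rate of each type,
    particles per unit time.  ``patch_weights`` optionally fixes each patch's
    per-type weight vector (rows = patches); when omitted, heterogeneous
    patches rotate through pairs of resource types so that the per-type mix
    varies across patches, and patchy-landscape patches produce all types
    equally.
    """

    n_types: int = 4
    rate_per_type: float = 16.0
    n_patches: int = 9
    patch_radius: float = 0.09
    background: float = 0.03  # heterogeneous landscapes only
    patch_weights: tuple | None = None


def _patch_centres(n: int, rng: np.random.Generator) -> list:
    """Jittered-grid centres: good arena coverage, still stochastic.

    The jitter is kept small enough that patches of the default radius can
    never overlap or merge: discrete patches are the premise of the patchy
    and heterogeneous scenarios.
    """
    side = int(np.ceil(np.sqrt(n)))
    cells = [(i, j) for i in range(side) for j in range(side)][:n]
    centres = []
    for (i, j) in cells:
        jitter = rng.uniform(-0.1, 0.1, size=2) / side
        centres.append((float(wrap((i + 0.5) / side + jitter[0])),
                        float(wrap((j + 0.5) / side + jitter[1]))))
    return centres


def make_landscape(kind: LandscapeKind, params: LandscapeParams | None = None,
                   seed: int = 0) -> Landscape:
    """Construct one of the three landscape scenarios.

    Deterministic given ``seed`` (which only controls patch placement).
    """
    params = params or LandscapeParams()
    rng = np.random.default_rng([seed, 0x1A2D])
    rates = tuple(float(params.rate_per_type) for _ in range(params.n_types))

    if kind == "homogeneous":
        return Landscape(kind="homogeneous", rates=rates, background=1.0)

    if params.n_patches < 1:
        raise ConfigurationError("patchy/heterogeneous landscapes need >= 1 patch")
    centres = _patch_centres(params.n_patches, rng)

    if kind == "patchy":
        weights = params.patch_weights or tuple(
            tuple(1.0 for _ in range(params.n_types))
            for _ in range(params.n_patches)
        )
        patches = tuple(Patch(cx, cy, params.patch_radius, tuple(w))
                        for (cx, cy), w in zip(centres, weights))
        return Landscape(kind="patchy", rates=rates, patches=patches,
                         background=0.0)

    if kind == "heterogeneous":
        if params.patch_weights is not None:
            weights = params.patch_weights
        else:
            # patch p produces the type pair {p mod T, (p+1) mod T}
            weights = []
            for p in range(params.n_patches):
                w = [0.0] * params.n_types
                w[p % params.n_types] = 1.0
                w[(p + 1) % params.n_types] = 1.0
                weights.append(tuple(w))
            weights = tuple(weights)
        patches = tuple(Patch(cx, cy, params.patch_radius, tuple(w))
                        for (cx, cy), w in zip(centres, weights))
        return Landscape(kind="heterogeneous", rates=rates, patches=patches,
                         background=params.background)

    raise ConfigurationError(f"unknown landscape kind: {kind!r}")


# ---------------------------------------------------------------------------
# resource particles
# ---------------------------------------------------------------------------

#: column order for particle tables (TSV export uses the same order)
PARTICLE_COLUMNS = ["id", "rtype", "x", "y", "created_at",
                    "consumed_by", "consumed_at"]


def sample_resource_events(landscape: Landscape, horizon: float, seed: int,
                           t0: float = 0.0, id_start: int = 0) -> pd.DataFrame:
    """Realise the space-time Poisson stream of resource production.

    Returns a particle table (columns :data:`PARTICLE_COLUMNS`) with events
    sorted by creation time; ``consumed_by``/``consumed_at`` start unset.
    Bit-reproducible for a given ``seed``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    rng = np.random.default_rng([seed, 0x9E50])
    rows = []
    for rtype in range(landscape.n_types):
        n = rng.poisson(landscape.total_rate(rtype) * horizon)
        times = np.sort(rng.uniform(t0, t0 + horizon, size=n))
        for t in times:
            x, y = landscape.sample_point(rtype, rng)
            rows.append((rtype, x, y, float(t)))
    rows.sort(key=lambda r: r[3])
    df = pd.DataFrame(rows, columns=["rtype", "x", "y", "created_at"])
    df.insert(0, "id", np.arange(id_start, id_start + len(df)))
    df["consumed_by"] = -1
    df["consumed_at"] = np.nan
    return df[PARTICLE_COLUMNS]


def particles_to_tsv(particles: pd.DataFrame, path) -> None:
    particles[PARTICLE_COLUMNS].to_csv(path, sep="\t", index=False)


def particles_from_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")[PARTICLE_COLUMNS]


# ---------------------------------------------------------------------------
# consumer niches
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NicheMatrix:
    """Binary species x resource-type usage table."""

    usage: np.ndarray  # (n_species, n_types) bool

    def __post_init__(self):
        usage = np.asarray(self.usage, dtype=bool)
        object.__setattr__(self, "usage", usage)
        if usage.ndim != 2:
            raise ConfigurationError("niche usage must be a 2-D table")
        if not usage.any(axis=1).all():
            raise ConfigurationError("every species must use >= 1 resource type")

    @property
    def n_species(self) -> int:
        return self.usage.shape[0]

    @property
    def n_types(self) -> int:
        return self.usage.shape[1]

    def uses(self, species: int, rtype: int) -> bool:
        return bool(self.usage[species, rtype])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"usage": self.usage.astype(int).tolist()}, fh)

    @classmethod
    def from_json(cls, path) -> "NicheMatrix":
        with open(path) as fh:
            return cls(np.array(json.load(fh)["usage"], dtype=bool))


def default_niche(n_species: int = 8, n_types: int = 4) -> NicheMatrix:
    """Default niche: species ``s`` uses types ``{s//2 mod T, (s//2+1) mod T}``.

    With 8 species on 4 types this yields species pairs of all three overlap
    classes: species 0 and 1 overlap completely, 0 and 2 partially, 0 and 4
    not at all.  Adjacent species indices share identical niches, so that
    under the mixed dispersal regime (first half of the species short-range,
    second half long-range) complete competitive equivalence only occurs
    *within* a dispersal class: neutral drift between equivalent species
    then cannot flip the community between short- and long-range dominance.
    """
    usage = np.zeros((n_species, n_types), dtype=bool)
    for s in range(n_species):
        usage[s, (s // 2) % n_types] = True
        usage[s, (s // 2 + 1) % n_types] = True
    return NicheMatrix(usage)


OverlapClass = Literal["none", "partial", "complete"]


def niche_overlap_class(sp_i: int, sp_j: int, niche: NicheMatrix) -> OverlapClass:
    """Classify a species pair by shared resource use.

    ``none`` when the usage rows are disjoint, ``complete`` when identical,
    ``partial`` otherwise.
    """
    for s in (sp_i, sp_j):
        if not 0 <= s < niche.n_species:
            raise KeyError(f"unknown species id {s}")
    a = niche.usage[sp_i]
    b = niche.usage[sp_j]
    if not np.any(a & b):
        return "none"
    if np.array_equal(a, b):
        return "complete"
    return "partial"
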