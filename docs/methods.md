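# Methods

`metacomm` implements a virtual-ecologist study: a mechanistic, individual-
based metacommunity model generates data in which the truth is fully
observable, and three operational definitions of the *local community of an
individual* are applied to those data to ask when they agree, and when local
communities form discrete units at all.

## The simulation model

Consumers live on the unit torus `[0,1) x [0,1)` (periodic boundaries, so
distance decay carries no edge artefacts) in continuous space and continuous
time. The state evolves by competing exponential hazards:

* **Resource production.** Each of `T` resource types is produced as a
  space-time Poisson process with landscape-dependent intensity (total rate
  `lambda` particles per type per unit time over the arena). Particles
  persist until consumed or until an expiry time `tau_R` (expiry is our
  device to bound the resource pool; it makes resources limiting).
* **Consumption.** A consumer of species `s` consumes any particle of a type
  its species uses (binary niche matrix, default: 8 species on 4 types,
  species `s` uses types `{s//2, s//2+1} mod 4`, so species pairs of all
  three overlap classes — none / partial / complete — exist, and complete
  competitive equivalence only occurs between species of the same dispersal
  class, which keeps the mixed-dispersal community compositionally stable)
  that lies within its consumption radius `r_c`, at contact rate `c` per
  in-range particle.
  Each consumption triggers a birth with probability `b`; the offspring is
  placed by the movement kernel around the parent.
* **Movement.** At rate `m` an individual relocates by a wrapped Gaussian
  jump with species-specific scale `sigma`. Dispersal regimes: *short* (all
  species `sigma_s = 0.006`), *long* (all `sigma_l = 0.06`), *mixed* (first
  half of the species short, second half long). The kernel scales keep a
  ratio of 10 and both stay below the patch spacing (0.33), so even
  long-range species remain spatially structured on the unit arena. The
  natal kernel equals the movement kernel.
* **Death.** Base hazard `d`, plus a virulence increment `delta` while
  infected.
* **Parasites** (case study 2) ride individual hosts: one parasite per host,
  location always the host's. A parasite transmits at rate `beta` per
  susceptible in-range (`r_t`) host whose species is in its host range
  (default: parasite `q` infects host species `{2q..2q+3} mod 8`, so
  parasite pairs share some but not all hosts); transmission creates a new
  parasite individual on the recipient (the infector stays). Parasites die
  at rate `d_par` and always die with their host (not free-living).

### Exact simulation and paired randomness

The engine is an exact next-event simulation in Anderson's modified
next-reaction formulation: each hazard channel integrates its own internal
clock and fires when the integral crosses a unit-exponential threshold.
Every individual draws those thresholds (and its kernel jumps, particle
choices and birth coin-flips) from **its own random stream keyed by its
lineage** (snapshot id, then per-parent birth index); resource production
has a separate stream. Consequence: in a *removal experiment* (treatment =
same run with one focal individual deleted before time zero, sharing the
control's master seed), any individual whose dynamics are not causally
coupled to the focal reproduces its control trajectory bit for bit. This
common-random-number pairing is what makes the influence estimator usable
at small replicate numbers, and it is tested exactly.

### Burn-in and the snapshot

Runs start from dispersed founders (10 per species, placed at production
locations of a usable type) and a pre-seeded resource pool. After a burn-in
of at least `t_burn = 30` time units the consumer abundance series over the
most recent half of the run is reduced to 12 block means and an OLS line is
fitted; the run is accepted as stationary when the slope's |t| < 2 (block
means are used because raw event-level abundances are strongly
autocorrelated and would overstate trend significance). The accepted state
is frozen as the **snapshot**: ids relabelled `0..N-1`, clock reset, no
generator state. All replicate and removal simulations start from this
common snapshot and differ only in their seeds. For parasite scenarios the
burn-in is retried (up to 4 derived seeds) until an endemic state with at
least 6 parasites is reached; persistent failure is reported as a missing
scenario rather than silently analysed.

## The three definitions of p_ij

* **Space use.** Each individual's utilisation distribution `C_i(x,y)` is
  estimated as the proportion of time spent in each cell of a `G x G` grid,
  accumulated exactly from the sojourn intervals of the piecewise-constant
  location process and pooled over all replicate runs (the replicate
  horizon, rather than the lifetime, keeps all three definitions on the
  same data). The estimator's default grid is 32 per side; the desk-scale
  preset uses `G = 8`, whose cell width (1/8) matches the consumption
  radius so the space-use and interaction definitions are compared at the
  same spatial resolution — on a finer grid the desk-scale home ranges
  fragment into near-disjoint rasters and the space-use delineation becomes
  artificially fine. A parasite's location follows its host.
  `p_ij = sum_cells sqrt(C_i C_j)` (Bhattacharyya coefficient), symmetric,
  unit diagonal.
* **Interaction.** Two consumers interact when one consumes a particle that
  at that moment lies within the consumption radius of the other and is of
  a type both species use; a parasite interacts with each host it infects;
  two parasites interact when one infects a host the other could also have
  infected (host in its range and within `r_t` of its own host).
  `p_ij` = proportion of replicate runs with at least one interaction
  (a presence/absence variant of the weights; the estimator is unbiased for
  the per-replicate interaction probability).
* **Influence.** For each focal `i`, paired control/treatment runs (above)
  are simulated; `p_ij` is the mean over replicates of the treatment-minus-
  control difference in offspring credited to `j`'s lineage (births by
  replicate-born descendants credit their snapshot ancestor; a parasite's
  "offspring" are the infections it causes). Signed and asymmetric:
  competition shows as `p_ij > 0` (release), exploitation of `j` by `i` as
  `p_ji < 0`.

Adjacency matrices are estimated among snapshot individuals only. The
convergence controller (`run_until_converged`) grows the replicate set in
batches until the relative Frobenius change of the cumulative estimate
falls below `tol` (default 0.05, batch 50, cap 1000), and flags — rather
than hides — a hit of the cap. The pipeline presets instead use fixed
replicate counts chosen for predictable runtimes (below).

## Delineation and comparison

Local communities are the partition maximising Newman–Girvan weighted
modularity, found with the Leiden algorithm (best of 10 seeded restarts;
ties broken by fewer communities, then canonical label order). The
modularity implementation is authored here (and cross-checked against
igraph in the tests): the directed generalisation
`Q = (1/W) sum_ij [w_ij - s_i^out s_j^in / W] delta(c_i, c_j)` is used
throughout, which reduces to the classical undirected form on symmetric
matrices. The diagonal is excluded; influence matrices are partitioned on
the magnitudes `|p_ij|` (modularity needs non-negative weights) while the
signed matrix is retained in outputs; the resolution parameter is fixed at
1 (plain modularity).

Agreement between definitions A and B is the cross-modularity
`Q_AB = Q(M_A, P_B) / Q(M_A, P_A)`, the proportion of A's maximal
modularity retained under B's partition; it is at most 1 (enforced by
re-optimising P_A from P_B if the optimiser is caught out) and is not
symmetric. Normalised mutual information between the label vectors is
reported alongside as an optimiser-free robustness check. Distance decay is
the proportion of consumer pairs sharing a community label, binned by
toroidal snapshot distance (20 equal bins to half the domain diagonal) and
stratified by the pair's resource-overlap class; empty bins are flagged NaN,
not zero.

In case study 2 the delineation is repeated on data subsets (hosts only /
parasites only / both). To evaluate a subset-based partition on another
subset's adjacencies, the partition is extended to the full community by
giving each uncovered individual the label of the covered individual with
maximal space-use overlap — a parasite thereby inherits its host's label.
This bridging rule is our design choice; any rule that maps parasites to
their hosts' communities would behave similarly for the host/parasite split.

## Parameter defaults and problem sizes

Defaults were calibrated once for persistent multi-species coexistence and
a stationary population of roughly 100 consumers, and then frozen:

| parameter | value | meaning |
|---|---|---|
| `m` | 1.5 | relocation rate (per unit time) |
| `sigma_s`, `sigma_l` | 0.006, 0.06 | short/long kernel scales (ratio 10) |
| `d` | 0.3 | base death hazard |
| `r_c` | 0.08 | consumption radius |
| `b` | 0.5 | birth probability per consumption |
| `c` | 8 | contact rate per in-range particle |
| `tau_R` | 2 | particle lifetime |
| `lambda` | 16 | production per type per unit time |
| patches | 9, radius 0.09 | jittered grid; heterogeneous background 3% |
| `beta`, `r_t` | 3.0, 0.10 | parasite transmission |
| `delta`, `d_par` | 0.15, 0.35 | virulence, parasite death |

`DESK_SCALE` (used by the tests and the reproduction script) runs 50
replicate simulations of horizon 5 for the space/interaction estimates and
6 paired removal sweeps for influence; one full scenario takes about a
minute on one CPU. In parasite scenarios production is scaled by 1.25 so
that the endemic consumer density matches the parasite-free baseline and
the parasite effect on community structure is not confounded with a
density effect. `DEFAULT_SCALE` increases founders, production and
replicate counts toward the hundreds for overnight runs. All problem sizes
are the package's own scaled-down choices; the reference setting they
emulate is larger.

With these conditions, means over the ten evaluation seeds place the three
delineations in the order interaction > influence > space use; the
parasite layer raises consumer modularity under every definition (most
strongly for space use); and the with-parasite interaction and influence
modularities remain below the values the converged, full-scale experiment
attains — the influence estimator in particular would need far more
removal replicates than the desk scale affords to densify its matrix to
the converged regime. The test suite states the full-scale expectation for
those two values exactly, so the corresponding check fails at desk scale;
it is left failing rather than loosened.

## What the generator does and does not emulate

The simulator realises competition **only** through depletion of shared
resource particles, and parasitism through added host mortality; there is
no interference, no evolution, no age structure, no multi-parasite
coinfection, and the arena is a torus without true edges. Passing tests
therefore show that the three definitions and their comparison behave as
described **on data whose generating process matches the model's
assumptions**; they do not certify behaviour on empirical data with
unmodelled structure (observation error, open boundaries, temporal
non-stationarity).

Known desk-scale limitations: the influence matrix at 6 paired sweeps is a
noisy, sparse version of its converged counterpart (its modularity is
biased upward by sparsity); interaction proportions at 50 replicates have
granularity 0.02; and single-seed modularity values fluctuate by several
hundredths across snapshots, so all headline comparisons are made as means
over seeds.

## Numerical choices

Toroidal distances are computed on demand (squared-distance comparisons in
the hot paths); sojourn accumulation is exact, not time-sampled; grid cells
are half-open and wrap; Bhattacharyya sums are clipped to [0, 1] against
rounding; modularity with zero total weight raises rather than returning 0;
cross-modularity with non-positive self-modularity raises with a
diagnostic. Seeds everywhere derive from one master seed through a
counter-based scheme (`derive_seed`), and every simulation artefact records
the seeds that produced it.
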