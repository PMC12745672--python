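# metacomm

**Delineating local communities in simulated metacommunities.**

Metacommunity theory treats a regional species pool as a network of *local
communities* linked by dispersal — yet empirical studies rarely say what
spatial unit they mean by a local community, and real landscapes rarely
hand one over. `metacomm` is a virtual-ecologist toolkit for studying that
problem on data where the truth is known. It combines

1. an **agent-based metacommunity simulator** — consumers in continuous
   space and continuous time on a periodic arena, competing by depleting
   shared resource particles, with an optional host–parasite layer
   (local transmission, added host mortality);
2. three operational definitions of the **local community of a focal
   individual** `i`, each yielding a pairwise weight `p_ij`:
   * **space use** — the Bhattacharyya overlap of utilisation
     distributions, `p_ij = ∑ √(C_i C_j)`;
   * **interaction** — the proportion of replicate simulations in which
     `i` and `j` interact (co-consumption within reach, or infection);
   * **influence** — the mean treatment−control difference in the
     offspring of `j` when `i` is removed, from paired removal experiments
     sharing common random numbers;
3. the network machinery to turn the adjacency matrix `P = (p_ij)` into
   community delineations and to compare them: Newman–Girvan (directed,
   weighted) **modularity** `Q`, **Leiden** partitioning, the
   **cross-modularity** index `Q_AB = Q(M_A, P_B) / Q(M_A, P_A)`, and
   **distance decay** of community co-membership stratified by
   resource-niche overlap.

It is written for quantitative ecologists who want to test community-
delineation protocols against a known generating process before trusting
them on field data.

## Worked example

```python
from metacomm import Scenario, DESK_SCALE, run_scenario

res = run_scenario(Scenario(landscape="heterogeneous", dispersal="mixed"),
                   DESK_SCALE, seed=1)
print(res.report)
```

This burns a metacommunity in to stationarity (85 consumers of eight
species on a patchy-resource landscape for this seed), estimates all three
adjacency matrices from replicate simulations, partitions each with Leiden,
and prints:

```
modularity:
  space        Q = 0.432
  interaction  Q = 0.701
  influence    Q = 0.708
cross-modularity Q_AB (rows: matrix A, cols: partition B):
             space  interaction  influence
space        1.000        0.854      0.726
interaction  0.986        1.000      0.916
influence    0.872        0.913      1.000
NMI between partitions:
             space  interaction  influence
space        1.000        0.770      0.667
interaction  0.770        1.000      0.702
influence    0.667        0.702      1.000
```

Read: both network-based definitions delineate far more modular (more
"community-like") structure than shared space use; across replicate seeds
the interaction-based definition scores highest on average (mean Q ≈ 0.74
vs 0.70 for influence and 0.51 for space use over seeds 1–10), though at
single-seed level interaction and influence can tie, as here. The
cross-modularity matrix is asymmetric: the `space` *row* (space-use
adjacencies explained by the network definitions' partitions) is lower
than the `space` *column* (network adjacencies explained by the space-use
partition), because interaction- and influence-based communities are close
to being *refinements* of the broad space-use communities — interacting
requires sharing space, but sharing space does not imply interacting.
`res.decay` holds the distance-decay curves per definition and
niche-overlap class.

A thin CLI wraps the same pipeline: `metacomm simulate`, `metacomm
adjacency`, `metacomm partition`, `metacomm decay`, `metacomm case1`,
`metacomm case2`, `metacomm report` (see `metacomm --help`).

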