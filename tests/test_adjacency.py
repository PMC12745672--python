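"""Adjacency estimators: space use, interaction rules, influence, convergence."""

import numpy as np
import pytest

from conftest import consumer, make_mini_config, parasite, snap_of

from metacomm.adjacency import (
    AdjacencyMatrix,
    SpaceUseField,
    bhattacharyya_overlap,
    detect_interactions,
    estimate_space_use,
    influence_adjacency,
    interaction_adjacency,
    run_until_converged,
    space_use_adjacency,
)
from metacomm.fixtures import make_toy_eventlog
from metacomm.landscape import NicheMatrix, default_niche
from metacomm.simulator import run_replicate


def field_of(weights, grid=2, individual=0):
    return SpaceUseField(individual, grid, np.asarray(weights, dtype=float))


class TestSpaceUse:
    def test_never_moves_single_cell(self):
        log = make_toy_eventlog([], [dict(id=0, x=0.1, y=0.1)], horizon=3.0)
        f = estimate_space_use(log, 0, grid=4)
        assert f.weights[0, 0] == 1.0
        assert f.weights.sum() == 1.0

    def test_scripted_sojourns_match_hand_computation(self):
        # 2 time units in one cell, then 1 unit in another: weights (2/3, 1/3)
        script = [dict(time=2.0, kind="move", actor=0, x=0.75, y=0.25)]
        log = make_toy_eventlog(script, [dict(id=0, x=0.25, y=0.25)],
                                horizon=3.0)
        f = estimate_space_use(log, 0, grid=2)
        assert f.weights[0, 0] == pytest.approx(2 / 3)
        assert f.weights[1, 0] == pytest.approx(1 / 3)

    def test_death_truncates_alive_time(self):
        script = [dict(time=1.0, kind="move", actor=0, x=0.75, y=0.25),
                  dict(time=2.0, kind="death", actor=0)]
        log = make_toy_eventlog(script, [dict(id=0, x=0.25, y=0.25)],
                                horizon=10.0)
        f = estimate_space_use(log, 0, grid=2)
        # 1 unit in each of two cells out of 2 alive
        assert f.weights[0, 0] == pytest.approx(0.5)
        assert f.weights[1, 0] == pytest.approx(0.5)

    def test_pooling_over_replicates(self):
        log1 = make_toy_eventlog([], [dict(id=0, x=0.1, y=0.1)], horizon=1.0)
        log2 = make_toy_eventlog(
            [dict(time=0.0, kind="move", actor=0, x=0.9, y=0.9)],
            [dict(id=0, x=0.1, y=0.1)], horizon=3.0)
        f = estimate_space_use([log1, log2], 0, grid=2)
        assert f.weights[0, 0] == pytest.approx(0.25)
        assert f.weights[1, 1] == pytest.approx(0.75)

    def test_parasite_rides_host(self):
        # host moves at t=1; the parasite's field must follow it
        script = [dict(time=1.0, kind="move", actor=0, x=0.75, y=0.75)]
        log = make_toy_eventlog(
            script,
            [dict(id=0, x=0.25, y=0.25), dict(id=1, guild=1, host_id=0,
                                              x=0.25, y=0.25)],
            horizon=2.0)
        f = estimate_space_use(log, 1, grid=2)
        assert f.weights[0, 0] == pytest.approx(0.5)
        assert f.weights[1, 1] == pytest.approx(0.5)

    def test_zero_alive_time_rejected(self):
        log = make_toy_eventlog([], [dict(id=0, x=0.1, y=0.1)], horizon=1.0)
        with pytest.raises(ValueError):
            estimate_space_use(log, 99, grid=2)


class TestBhattacharyya:
    def test_identical_fields_give_one(self):
        f = field_of([[0.25, 0.25], [0.25, 0.25]])
        assert bhattacharyya_overlap(f, f) == pytest.approx(1.0)

    def test_disjoint_fields_give_zero(self):
        a = field_of([[1.0, 0.0], [0.0, 0.0]])
        b = field_of([[0.0, 0.0], [0.0, 1.0]], individual=1)
        assert bhattacharyya_overlap(a, b) == 0.0

    def test_half_overlap_worked_value(self):
        # (0.5, 0.5) vs (1, 0) on two cells: sum sqrt(0.5*1) = sqrt(0.5)
        a = field_of([[0.5, 0.5], [0.0, 0.0]])
        b = field_of([[1.0, 0.0], [0.0, 0.0]], individual=1)
        assert bhattacharyya_overlap(a, b) == pytest.approx(np.sqrt(0.5))

    def test_grid_mismatch_rejected(self):
        a = field_of([[0.5, 0.5], [0.0, 0.0]])
        b = SpaceUseField(1, 4, np.full((4, 4), 1 / 16))
        with pytest.raises(ValueError):
            bhattacharyya_overlap(a, b)

    def test_space_adjacency_unit_diagonal_symmetric(self):
        logs = [make_toy_eventlog(
            [dict(time=1.0, kind="move", actor=0, x=0.9, y=0.9)],
            [dict(id=0, x=0.1, y=0.1), dict(id=1, x=0.12, y=0.1)],
            horizon=2.0)]
        adj = space_use_adjacency(logs, [0, 1], grid=4)
        assert np.allclose(np.diag(adj.weights), 1.0)
        assert np.allclose(adj.weights, adj.weights.T)
        assert ((adj.weights >= 0) & (adj.weights <= 1)).all()


def two_consumer_script(neighbour_xy, rtype=0, species_j=0):
    """Consumer 0 consumes particle 100 at (0.5, 0.5); individual 1 sits at
    ``neighbour_xy``."""
    individuals = [dict(id=0, species=0, x=0.5, y=0.5),
                   dict(id=1, species=species_j, x=neighbour_xy[0],
                        y=neighbour_xy[1])]
    particles = [dict(id=100, rtype=rtype, x=0.5, y=0.5)]
    script = [dict(time=0.5, kind="consume", actor=0, object=100,
                   x=0.5, y=0.5, species=0)]
    return make_toy_eventlog(script, individuals, particles, horizon=1.0)


class TestInteractionRules:
    niche = NicheMatrix(np.array([[1, 0], [0, 1]], dtype=bool))

    def test_in_range_co_user_detected(self):
        log = two_consumer_script((0.52, 0.5))  # distance 0.02 < r_c
        pairs = detect_interactions(log, default_niche(2, 2), r_c=0.05)
        assert pairs == {(0, 1)}

    def test_out_of_range_not_detected(self):
        log = two_consumer_script((0.8, 0.5))
        pairs = detect_interactions(log, default_niche(2, 2), r_c=0.05)
        assert pairs == set()

    def test_non_user_species_not_detected(self):
        # species 1 cannot use resource type 0: no interaction even in range
        log = two_consumer_script((0.52, 0.5), rtype=0, species_j=1)
        pairs = detect_interactions(log, self.niche, r_c=0.05)
        assert pairs == set()

    def test_infection_is_an_interaction(self):
        individuals = [dict(id=0, x=0.5, y=0.5),
                       dict(id=1, guild=1, host_id=0, x=0.5, y=0.5),
                       dict(id=2, x=0.52, y=0.5)]
        script = [dict(time=0.3, kind="infect", actor=1, object=2,
                       x=0.52, y=0.5, species=0),
                  dict(time=0.3, kind="birth", actor=3, parent=1,
                       x=0.52, y=0.5, species=0)]
        log = make_toy_eventlog(script, individuals, horizon=1.0)
        pairs = detect_interactions(log, default_niche(2, 2),
                                    host_range=np.ones((1, 2), bool))
        assert (1, 2) in pairs

    def test_parasite_parasite_shared_potential_host(self):
        # q rides a host within r_t of the infection and could infect too
        individuals = [dict(id=0, x=0.5, y=0.5),
                       dict(id=1, guild=1, host_id=0, x=0.5, y=0.5),
                       dict(id=2, x=0.55, y=0.5),
                       dict(id=3, guild=1, species=0, host_id=2,
                            x=0.55, y=0.5),
                       dict(id=4, x=0.52, y=0.5)]
        script = [dict(time=0.3, kind="infect", actor=1, object=4,
                       x=0.52, y=0.5, species=0),
                  dict(time=0.3, kind="birth", actor=5, parent=1,
                       x=0.52, y=0.5, species=0)]
        log = make_toy_eventlog(script, individuals, horizon=1.0)
        pairs = detect_interactions(log, default_niche(2, 2),
                                    host_range=np.ones((1, 2), bool),
                                    r_t=0.1)
        assert (1, 3) in pairs
        # and not when the other parasite is out of transmission range
        pairs2 = detect_interactions(log, default_niche(2, 2),
                                     host_range=np.ones((1, 2), bool),
                                     r_t=0.01)
        assert (1, 3) not in pairs2


class TestInteractionAdjacency:
    def test_proportion_of_replicates(self):
        sets = [{(0, 1)}] * 3 + [set()] * 7
        adj = interaction_adjacency(sets, [0, 1, 2])
        assert adj.weights[0, 1] == pytest.approx(0.3)
        assert adj.weights[1, 0] == pytest.approx(0.3)
        assert adj.weights[0, 2] == 0.0
        assert ((adj.weights >= 0) & (adj.weights <= 1)).all()

    def test_empty_replicate_list_rejected(self):
        with pytest.raises(ValueError):
            interaction_adjacency([], [0, 1])

    def test_interaction_requires_space_overlap(self):
        # any interacting pair must share support of space use at a grid
        # coarser than the interaction reach
        cfg = make_mini_config(n_species=2, n_types=2, rate=40.0, m=1.5,
                               d=0.3, b=0.5, rc=0.06,
                               usage=[[1, 1], [1, 1]])
        snap = snap_of([consumer(i, i % 2, 0.2 + 0.06 * i, 0.5)
                        for i in range(10)])
        logs = [run_replicate(cfg, snap, 4.0, s) for s in range(10)]
        from metacomm.adjacency import interaction_pairs
        pair_sets = [detect_interactions(log, cfg.niche, r_c=0.06)
                     for log in logs]
        space = space_use_adjacency(logs, list(range(10)), grid=6)
        pos = {i: k for k, i in enumerate(space.ids)}
        seen = False
        for pairs in pair_sets:
            for a, b in pairs:
                if a in pos and b in pos:
                    seen = True
                    assert space.weights[pos[a], pos[b]] > 0
        assert seen, "expected at least one interaction in the test runs"


class TestInfluence:
    def test_single_individual_empty_matrix(self):
        cfg = make_mini_config(rate=10.0, d=0.2, b=0.5, rc=0.05)
        snap = snap_of([consumer(0)])
        adj = influence_adjacency(cfg, snap, horizon=2.0, n_replicates=2,
                                  seed=0)
        assert adj.weights.shape == (1, 1)
        assert adj.weights[0, 0] == 0.0

    def test_uncoupled_pair_exactly_zero(self):
        # focal cannot consume and there is no parasite layer: every
        # treatment equals its control for the other individual
        from dataclasses import replace
        cfg = make_mini_config(n_species=2, rate=25.0, m=1.0, d=0.3, b=0.7,
                               rc=0.06)
        rc = cfg.rates.consumption_radius.copy()
        rc[0] = 0.0
        cfg = replace(cfg, rates=replace(cfg.rates, consumption_radius=rc))
        snap = snap_of([consumer(0, 0, 0.2, 0.2), consumer(1, 1, 0.8, 0.8)])
        adj = influence_adjacency(cfg, snap, horizon=4.0, n_replicates=3,
                                  seed=7)
        assert adj.weights[0, 1] == 0.0

    def test_signed_and_possibly_asymmetric_container(self):
        adj = AdjacencyMatrix("influence", (0, 1),
                              np.array([[0.0, -1.0], [2.0, 0.0]]),
                              symmetric=False, signed=True)
        w = adj.working_weights()
        assert (w >= 0).all() and w[0, 1] == 1.0 and w[1, 0] == 2.0


class _FakeEstimator:
    """Estimate converging at rate 1/n around a fixed matrix."""

    definition = "space"

    def __init__(self, noise=1.0):
        self.n_replicates = 0
        self.noise = noise
        self.target = np.eye(4)

    def add_replicate(self, seed):
        self.n_replicates += 1

    def matrix(self):
        rng = np.random.default_rng(self.n_replicates)
        return self.target + self.noise * rng.random((4, 4)) / self.n_replicates

    def to_adjacency(self, provenance=None):
        return AdjacencyMatrix("space", (0, 1, 2, 3), self.matrix(),
                               symmetric=False, provenance=provenance or {})


class TestConvergenceController:
    def test_deterministic_estimator_stops_after_two_batches(self):
        est = _FakeEstimator(noise=0.0)
        adj, info = run_until_converged(est, seed=0, batch=3, tol=0.05)
        assert info.converged
        assert info.replicates == 6
        assert info.deltas[-1] < 0.05

    def test_flagged_when_budget_exhausted(self):
        est = _FakeEstimator(noise=500.0)
        with pytest.warns(RuntimeWarning, match="not converged"):
            adj, info = run_until_converged(est, seed=0, batch=2, tol=1e-6,
                                            max_replicates=8)
        assert not info.converged
        assert info.replicates == 8

    def test_tightening_tol_never_uses_fewer_replicates(self):
        used = []
        for tol in (0.2, 0.1, 0.05, 0.025):
            est = _FakeEstimator(noise=2.0)
            _, info = run_until_converged(est, seed=0, batch=1, tol=tol,
                                          max_replicates=400)
            used.append(info.replicates)
        assert all(b >= a for a, b in zip(used, used[1:]))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            run_until_converged(_FakeEstimator(), seed=0, batch=0, tol=0.1)


class TestAdjacencyIO:
    def test_csv_roundtrip(self, tmp_path):
        w = np.array([[1.0, 0.3], [0.3, 1.0]])
        adj = AdjacencyMatrix("space", (10, 11), w, symmetric=True,
                              provenance={"seed": 1})
        adj.to_csv(tmp_path / "m.csv")
        back = AdjacencyMatrix.from_csv(tmp_path / "m.csv")
        assert back.ids == (10, 11)
        assert np.allclose(back.weights, w)
        assert back.symmetric

    def test_edgelist_excludes_diagonal(self, tmp_path):
        import pandas as pd
        w = np.array([[1.0, 0.5], [0.5, 1.0]])
        adj = AdjacencyMatrix("space", (0, 1), w, symmetric=True)
        adj.to_edgelist(tmp_path / "e.tsv")
        df = pd.read_csv(tmp_path / "e.tsv", sep="\t")
        assert len(df) == 2
        assert (df.i != df.j).all()
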