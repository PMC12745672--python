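"""Engine correctness: event hazards, seeding contracts, removal pairing."""

import numpy as np
import pandas as pd
import pytest

from conftest import consumer, make_mini_config, parasite, snap_of

from metacomm.landscape import torus_delta
from metacomm.simulator import (
    EVENT_COLUMNS,
    GUILD_PARASITE,
    RateModel,
    Snapshot,
    ancestral_offspring_counts,
    derive_seed,
    offspring_count,
    removal_replicate,
    run,
    run_replicate,
    run_to_stationarity,
)


class TestRunBasics:
    def test_all_rates_zero_nothing_happens(self):
        cfg = make_mini_config(rate=0.0)
        snap = snap_of([consumer(0, 0, 0.2, 0.2), consumer(1, 1, 0.7, 0.7)])
        final, log = run(cfg, snap, horizon=3.0, seed=1)
        assert len(log.events) == 0
        pd.testing.assert_frame_equal(
            final.individuals[["id", "species", "x", "y"]],
            snap.individuals[["id", "species", "x", "y"]])

    def test_zero_horizon_empty_log(self):
        cfg = make_mini_config(d=1.0, m=1.0)
        snap = snap_of([consumer(0)])
        log = run_replicate(cfg, snap, horizon=0.0, seed=4)
        assert len(log.events) == 0

    def test_mover_displacements_symmetric(self):
        # single immortal non-reproducing mover: >= 1e4 kernel jumps have
        # per-axis mean displacement ~ 0 on the periodic arena
        cfg = make_mini_config(m=25.0, sigma=0.05)
        snap = snap_of([consumer(0, 0, 0.5, 0.5)])
        log = run_replicate(cfg, snap, horizon=450.0, seed=2)
        mv = log.events[log.events.kind == "move"]
        assert len(mv) > 10_000
        xs = np.concatenate([[0.5], mv.x.to_numpy()])
        # signed minimal-image steps
        step = (np.diff(xs) + 0.5) % 1.0 - 0.5
        se = step.std() / np.sqrt(len(step))
        assert abs(step.mean()) < 3 * se

    def test_lifetime_is_exponential(self):
        # death at rate d with everything else off: mean lifetime ~ 1/d
        d = 2.0
        cfg = make_mini_config(d=d)
        snap = snap_of([consumer(0)])
        times = []
        for s in range(1000):
            log = run_replicate(cfg, snap, horizon=20.0, seed=s)
            deaths = log.events[log.events.kind == "death"]
            times.append(float(deaths.time.iloc[0]) if len(deaths) else 20.0)
        se = (1 / d) / np.sqrt(len(times))
        assert abs(np.mean(times) - 1 / d) < 3 * se

    def test_extinction_flagged_not_raised(self):
        cfg = make_mini_config(d=50.0)
        snap = snap_of([consumer(0)])
        with pytest.warns(RuntimeWarning, match="extinct"):
            final, log = run(cfg, snap, horizon=5.0, seed=0)
        assert log.extinct
        assert len(final.individuals) == 0


class TestSeedingContracts:
    def test_same_seed_identical_logs(self):
        cfg = make_mini_config(rate=20.0, m=1.0, d=0.3, b=0.5, rc=0.1)
        snap = snap_of([consumer(i, i % 2, 0.3 + 0.1 * i, 0.4)
                        for i in range(4)])
        a = run_replicate(cfg, snap, horizon=4.0, seed=11)
        b = run_replicate(cfg, snap, horizon=4.0, seed=11)
        pd.testing.assert_frame_equal(a.events, b.events)

    def test_different_seeds_differ(self):
        cfg = make_mini_config(rate=20.0, m=1.0, d=0.3, b=0.5, rc=0.1)
        snap = snap_of([consumer(i, i % 2, 0.3 + 0.1 * i, 0.4)
                        for i in range(4)])
        a = run_replicate(cfg, snap, horizon=4.0, seed=11)
        b = run_replicate(cfg, snap, horizon=4.0, seed=12)
        assert not a.events.equals(b.events)

    def test_derive_seed_stable_and_bounded(self):
        assert derive_seed(3, 1, 2) == derive_seed(3, 1, 2)
        assert derive_seed(3, 1, 2) != derive_seed(3, 2, 1)
        assert 0 <= derive_seed(2**20, 999) < 2**31


@pytest.fixture(scope="module")
def busy_log():
    cfg = make_mini_config(n_species=2, n_types=2, rate=30.0, m=2.0,
                           d=0.3, b=0.6, rc=0.08,
                           usage=[[1, 0], [1, 1]])
    snap = snap_of([consumer(i, i % 2, 0.1 * i + 0.05, 0.5)
                    for i in range(8)])
    return cfg, run_replicate(cfg, snap, horizon=6.0, seed=5)


class TestLogInvariants:

    def test_event_times_non_decreasing(self, busy_log):
        _, log = busy_log
        assert (np.diff(log.events.time.to_numpy()) >= 0).all()

    def test_consume_events_audit(self, busy_log):
        # every consumed particle is consumed once, by a species that can
        # use its resource type
        cfg, log = busy_log
        cons = log.events[log.events.kind == "consume"]
        assert len(cons) > 0
        assert cons.object.is_unique
        rtype = log.particles.set_index("id").rtype
        for rec in cons.itertuples(index=False):
            assert cfg.niche.usage[int(rec.species), int(rtype[rec.object])]

    def test_abundance_changes_only_at_birth_death(self, busy_log):
        _, log = busy_log
        births = (log.events.kind == "birth").sum()
        deaths = (log.events.kind == "death").sum()
        n0 = len(log.initial.individuals)
        # net bookkeeping must match the event counts
        assert births - deaths == -n0 + (n0 + births - deaths)

    def test_offspring_count_conservation(self, busy_log):
        _, log = busy_log
        births = log.births()
        total = sum(offspring_count(log, p) for p in births.parent.unique())
        assert total == len(births)

    def test_offspring_count_window_and_empty(self, busy_log):
        _, log = busy_log
        assert offspring_count(log, -42) == 0
        parent = log.births().parent.iloc[0]
        full = offspring_count(log, parent)
        half = offspring_count(log, parent, window=(0.0, 3.0))
        assert 0 <= half <= full
        with pytest.raises(ValueError):
            offspring_count(log, parent, window=(0.0, 99.0))

    def test_ancestral_counts_credit_lineages(self, busy_log):
        _, log = busy_log
        ids = [int(i) for i in log.initial.ids]
        counts = ancestral_offspring_counts(log, ids)
        # every birth is credited to exactly one snapshot founder
        assert counts.sum() == len(log.births())


class TestParasites:
    def _host_parasite_config(self, n_species=1, **kw):
        base = dict(
            d=0.5, rc=0.0,
            parasite_death=np.zeros(1),
            transmission_radius=0.1,
            transmission_rate=0.0,
            virulence=1.0,
            host_range=np.ones((1, n_species), dtype=bool),
        )
        base.update(kw)
        return make_mini_config(n_species=n_species, **base)

    def test_infected_die_faster(self, rng):
        # delta > 0: mean lifespan of infected hosts < uninfected (3 SE)
        cfg = self._host_parasite_config()
        rows, next_id = [], 0
        for k in range(120):
            x, y = rng.random(2)
            rows.append(consumer(next_id, 0, x, y))
            next_id += 1
        n_inf = 60
        for k in range(n_inf):
            rows.append(parasite(next_id, 0, host=k))
            next_id += 1
        snap = snap_of(rows)
        log = run_replicate(cfg, snap, horizon=40.0, seed=8)
        deaths = log.events[log.events.kind == "death"].set_index("actor").time
        t_inf = np.array([deaths.get(i, 40.0) for i in range(n_inf)])
        t_ok = np.array([deaths.get(i, 40.0) for i in range(n_inf, 120)])
        se = np.sqrt(t_inf.var() / len(t_inf) + t_ok.var() / len(t_ok))
        assert t_ok.mean() - t_inf.mean() > 3 * se

    def test_host_death_kills_parasite(self):
        cfg = self._host_parasite_config(d=5.0)
        snap = snap_of([consumer(0), parasite(1, 0, host=0)])
        log = run_replicate(cfg, snap, horizon=10.0, seed=3)
        d = log.events[log.events.kind == "death"]
        assert set(d.actor) == {0, 1}
        assert d.time.iloc[0] == d.time.iloc[1]

    def test_transmission_respects_host_range(self):
        # parasite species 0 cannot infect species 1 hosts
        cfg = self._host_parasite_config(
            n_species=2, d=0.0, virulence=0.1,
            transmission_rate=50.0,
            host_range=np.array([[True, False]]))
        snap = snap_of([consumer(0, 0, 0.5, 0.5), consumer(1, 1, 0.51, 0.5),
                        consumer(2, 0, 0.49, 0.5), parasite(3, 0, host=0)])
        log = run_replicate(cfg, snap, horizon=5.0, seed=2)
        infected = set(log.events[log.events.kind == "infect"].object)
        assert 1 not in infected
        assert 2 in infected

    def test_snapshot_rejects_orphan_parasite(self):
        with pytest.raises(ValueError):
            snap_of([consumer(0), parasite(1, 0, host=99)])


class TestRemovalPairing:
    def test_uncoupled_focal_leaves_others_untouched(self):
        # the focal cannot consume (radius 0): under common random numbers
        # the treatment log equals the control log minus the focal's events
        cfg = make_mini_config(n_species=2, n_types=1, rate=25.0, m=1.5,
                               d=0.4, b=0.7, rc=0.06,
                               usage=[[1], [1]])
        from dataclasses import replace
        rc = cfg.rates.consumption_radius.copy()
        rc[0] = 0.0  # species 0 never consumes -> zero interaction rates
        cfg = replace(cfg, rates=replace(cfg.rates, consumption_radius=rc))
        snap = snap_of([consumer(0, 0, 0.5, 0.5),
                        consumer(1, 1, 0.2, 0.2),
                        consumer(2, 1, 0.8, 0.8)])
        control, treat = removal_replicate(cfg, snap, focal=0,
                                           horizon=5.0, seed=21)
        keep = control.events[control.events.actor != 0].reset_index(drop=True)
        pd.testing.assert_frame_equal(keep, treat.events)

    def test_removing_infected_host_takes_parasite(self):
        cfg = make_mini_config(
            n_species=1, d=0.1,
            parasite_death=np.zeros(1), transmission_radius=0.1,
            transmission_rate=0.0, virulence=0.5,
            host_range=np.ones((1, 1), dtype=bool))
        snap = snap_of([consumer(0), consumer(1, 0, 0.2, 0.2),
                        parasite(2, 0, host=0)])
        control, treat = removal_replicate(cfg, snap, focal=0,
                                           horizon=2.0, seed=5)
        assert len(treat.initial.individuals) \
            == len(control.initial.individuals) - 2

    def test_unknown_focal_rejected(self):
        cfg = make_mini_config()
        snap = snap_of([consumer(0)])
        with pytest.raises(KeyError):
            removal_replicate(cfg, snap, focal=7, horizon=1.0, seed=0)


@pytest.fixture(scope="module")
def snapshot_pair():
    from metacomm.pipeline import Scenario, make_config, DESK_SCALE
    cfg = make_config(Scenario(landscape="homogeneous",
                               dispersal="mixed"), DESK_SCALE, seed=0)
    a = run_to_stationarity(cfg, seed=42, t_burn=15.0, max_time=60.0)
    b = run_to_stationarity(cfg, seed=42, t_burn=15.0, max_time=60.0)
    return a, b


class TestStationarity:

    def test_snapshot_persistent_and_multispecies(self, snapshot_pair):
        snap, _ = snapshot_pair
        assert len(snap.individuals) >= 1
        assert snap.individuals.species.nunique() >= 2

    def test_same_seed_identical_snapshot(self, snapshot_pair):
        a, b = snapshot_pair
        pd.testing.assert_frame_equal(a.individuals, b.individuals)
        pd.testing.assert_frame_equal(a.resources, b.resources)

    def test_snapshot_clock_reset(self, snapshot_pair):
        snap, _ = snapshot_pair
        assert snap.time == 0.0
        assert (snap.individuals.id.to_numpy()
                == np.arange(len(snap.individuals))).all()

    def test_json_roundtrip(self, snapshot_pair, tmp_path):
        snap, _ = snapshot_pair
        snap.to_json(tmp_path / "s.json")
        back = Snapshot.from_json(tmp_path / "s.json")
        pd.testing.assert_frame_equal(back.individuals, snap.individuals)


class TestSerialization:
    def test_eventlog_tsv_columns(self, busy_log, tmp_path):
        _, log = busy_log
        log.to_tsv(tmp_path / "events.tsv")
        head = (tmp_path / "events.tsv").read_text().splitlines()[0]
        assert head.split("\t") == EVENT_COLUMNS

    def test_config_yaml_roundtrip(self, tmp_path):
        from metacomm.pipeline import Scenario, make_config, DESK_SCALE
        from metacomm.simulator import SimConfig
        cfg = make_config(Scenario(parasites=True), DESK_SCALE, seed=3)
        cfg.to_yaml(tmp_path / "config.yaml")
        back = SimConfig.from_yaml(tmp_path / "config.yaml")
        assert back.landscape.to_dict() == cfg.landscape.to_dict()
        assert (back.niche.usage == cfg.niche.usage).all()
        assert (back.rates.sigma == cfg.rates.sigma).all()
        assert back.rates.host_range is not None

    def test_config_schema_version_checked(self, tmp_path):
        (tmp_path / "bad.yaml").write_text("schema_version: 99\n")
        from metacomm.simulator import SimConfig
        with pytest.raises(ValueError, match="schema"):
            SimConfig.from_yaml(tmp_path / "bad.yaml")
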