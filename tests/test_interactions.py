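"""Contact detection, death calling, outcome assignment and statistics."""

import numpy as np
import pandas as pd
import pytest

import nkwell3d as nk
from nkwell3d.config import ContactConfig, SimulationConfig
from nkwell3d.interactions import (
    DeathEvent,
    OUTCOME_CYTOLYTIC,
    OUTCOME_NONCYTOLYTIC,
    episodes_to_dataframe,
)
from nkwell3d.tracks import Track


def _static(pos, n, cell_id, cell_type, dt=2.0):
    return Track(cell_id, cell_type,
                 np.arange(n) * dt, np.tile(np.asarray(pos, float), (n, 1)))


def _pair_at_distance(d, n=5):
    nk_tr = _static([0, 0, 0], n, 0, "NK")
    tg_tr = _static([d, 0, 0], n, 10, "target")
    return [nk_tr], [tg_tr]


class TestDetectContacts:
    def test_constant_distance_inside_boundary(self):
        nks, tgs = _pair_at_distance(19.9, n=5)
        eps = nk.detect_contacts(nks, tgs, ContactConfig())
        assert len(eps) == 1
        e = eps[0]
        assert e.start_frame == 0 and e.end_frame == 4
        assert e.duration_min == pytest.approx(5 * 2.0)

    def test_boundary_equality_is_no_contact(self):
        nks, tgs = _pair_at_distance(20.0)
        assert nk.detect_contacts(nks, tgs, ContactConfig()) == []

    def test_matches_brute_force_scan(self):
        """Episode set identical to an exhaustive all-pairs distance scan."""
        rng = np.random.default_rng(13)
        cfg = ContactConfig()
        for _ in range(50):
            n_frames = 50
            nks = [Track(i, "NK", np.arange(n_frames) * 2.0,
                         rng.uniform(0, 80, (n_frames, 3))) for i in range(10)]
            tgs = [Track(100 + j, "target", np.arange(n_frames) * 2.0,
                         rng.uniform(0, 80, (n_frames, 3))) for j in range(5)]
            eps = nk.detect_contacts(nks, tgs, cfg)
            got = {(e.nk_id, e.target_id, e.start_frame, e.end_frame) for e in eps}
            expect = set()
            for a in nks:
                for b in tgs:
                    run = None
                    for f in range(n_frames):
                        if np.linalg.norm(a.pos[f] - b.pos[f]) < cfg.contact_radius:
                            run = [f, f] if run is None else [run[0], f]
                        elif run is not None:
                            expect.add((a.cell_id, b.cell_id, run[0], run[1]))
                            run = None
                    if run is not None:
                        expect.add((a.cell_id, b.cell_id, run[0], run[1]))
            assert got == expect

    def test_gap_tolerance_merges_runs(self):
        t = np.arange(10) * 2.0
        pos = np.zeros((10, 3))
        tg_pos = np.full((10, 3), [10.0, 0, 0])
        tg_pos[5] = [40.0, 0, 0]  # one-frame dropout above the radius
        nks = [Track(0, "NK", t, pos)]
        tgs = [Track(1, "target", t, tg_pos)]
        assert len(nk.detect_contacts(nks, tgs, ContactConfig())) == 2
        merged = nk.detect_contacts(nks, tgs, ContactConfig(gap_tolerance=1))
        assert len(merged) == 1
        assert (merged[0].start_frame, merged[0].end_frame) == (0, 9)

    def test_episodes_non_overlapping_per_pair(self):
        rng = np.random.default_rng(3)
        n_frames = 80
        nks = [Track(0, "NK", np.arange(n_frames) * 2.0,
                     np.cumsum(rng.normal(0, 8, (n_frames, 3)), axis=0) + 50)]
        tgs = [Track(1, "target", np.arange(n_frames) * 2.0,
                     np.full((n_frames, 3), 50.0))]
        eps = nk.detect_contacts(nks, tgs, ContactConfig())
        for e in eps:
            assert e.duration_min > 0
        spans = sorted((e.start_frame, e.end_frame) for e in eps)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            assert e1 < s2


class TestDetectTargetDeath:
    def test_constant_trace_no_death(self):
        cfg = ContactConfig()
        assert nk.detect_target_death(np.full(20, 100.0), cfg, dt=2.0) is None

    def test_step_drop_called_at_step_frame(self):
        cfg = ContactConfig()
        trace = np.concatenate([np.full(10, 100.0), np.full(10, 10.0)])
        ev = nk.detect_target_death(trace, cfg, dt=2.0, target_id=7)
        assert ev is not None
        assert ev.death_min == pytest.approx(10 * 2.0)
        assert ev.target_id == 7 and ev.source == "intensity-called"

    def test_transient_dip_ignored(self):
        cfg = ContactConfig()
        trace = np.full(20, 100.0)
        trace[8] = 5.0
        assert nk.detect_target_death(trace, cfg, dt=2.0) is None

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            nk.detect_target_death(np.ones(2), ContactConfig(), dt=2.0)


class TestAssignOutcomes:
    def _episode(self, nk_id, target_id, start, end, dt=2.0):
        return nk.ContactEpisode(
            nk_id=nk_id, target_id=target_id,
            start_frame=int(start / dt), end_frame=int(end / dt) - 1,
            start_min=start, end_min=end, duration_min=end - start,
        )

    def test_death_mid_episode_is_cytolytic(self):
        eps = [self._episode(0, 10, 20.0, 60.0)]
        deaths = [DeathEvent(10, 40.0)]
        out, tallies, un = nk.assign_outcomes(eps, deaths, ContactConfig())
        assert out[0].outcome == OUTCOME_CYTOLYTIC
        assert tallies.loc[0, ["contacts", "kills"]].tolist() == [1, 1]
        assert un == []

    def test_no_death_is_noncytolytic(self):
        eps = [self._episode(0, 10, 20.0, 60.0)]
        out, tallies, _ = nk.assign_outcomes(eps, [], ContactConfig())
        assert out[0].outcome == OUTCOME_NONCYTOLYTIC
        assert tallies.loc[0, "kills"] == 0

    def test_sequential_episodes_attribute_to_latest(self):
        """Two NK contact the same target; death 10 min after the second
        episode ends is credited to the second NK only."""
        e1 = self._episode(0, 10, 0.0, 30.0)
        e2 = self._episode(1, 10, 40.0, 70.0)
        deaths = [DeathEvent(10, 80.0)]
        out, tallies, _ = nk.assign_outcomes([e1, e2], deaths, ContactConfig())
        assert out[0].outcome == OUTCOME_NONCYTOLYTIC
        assert out[1].outcome == OUTCOME_CYTOLYTIC
        assert tallies.set_index("nk_id")["kills"].to_dict() == {0: 0, 1: 1}

    def test_death_outside_window_unattributed(self):
        eps = [self._episode(0, 10, 0.0, 20.0)]
        deaths = [DeathEvent(10, 60.0)]  # 40 min after end > 30 min window
        out, _, un = nk.assign_outcomes(eps, deaths, ContactConfig())
        assert out[0].outcome == OUTCOME_NONCYTOLYTIC
        assert len(un) == 1

    def test_kills_never_exceed_contacts(self):
        rng = np.random.default_rng(23)
        eps = [self._episode(int(rng.integers(5)), int(rng.integers(10, 14)),
                             float(s), float(s + 10))
               for s in rng.choice(np.arange(0, 400, 20), size=15, replace=False)]
        deaths = [DeathEvent(t, float(rng.uniform(0, 400))) for t in range(10, 14)]
        _, tallies, _ = nk.assign_outcomes(eps, deaths, ContactConfig())
        assert (tallies["kills"] <= tallies["contacts"]).all()


class TestInteractionStats:
    def _eps(self, durations, outcome):
        return [
            nk.ContactEpisode(nk_id=i, target_id=100 + i, start_frame=0,
                              end_frame=1, start_min=0.0, end_min=d,
                              duration_min=d, outcome=outcome)
            for i, d in enumerate(durations)
        ]

    def test_mean_and_sample_sd(self):
        eps = self._eps([10.0, 20.0, 30.0], OUTCOME_NONCYTOLYTIC)
        st = nk.interaction_stats(eps)
        assert st["mean_duration_min"] == pytest.approx(20.0)
        assert st["sd_duration_min"] == pytest.approx(10.0)  # ddof=1

    def test_identical_groups_p_near_one(self):
        eps = (self._eps([10.0, 20.0, 30.0], OUTCOME_CYTOLYTIC)
               + self._eps([10.0, 20.0, 30.0], OUTCOME_NONCYTOLYTIC))
        st = nk.interaction_stats(eps)
        assert st["duration_mannwhitney_p"] >= 0.95

    def test_exact_separated_groups(self):
        """{1,2,3} vs {4,5,6}: U = 0, exact two-sided p = 0.1."""
        eps = (self._eps([4.0, 5.0, 6.0], OUTCOME_CYTOLYTIC)
               + self._eps([1.0, 2.0, 3.0], OUTCOME_NONCYTOLYTIC))
        st = nk.interaction_stats(eps)
        assert st["duration_mannwhitney_p"] == pytest.approx(0.1)
        # statistic is min-or-max U depending on orientation
        assert st["duration_mannwhitney_U"] in (0.0, 9.0)

    def test_single_group_comparison_skipped(self):
        st = nk.interaction_stats(self._eps([5.0, 6.0], OUTCOME_NONCYTOLYTIC))
        assert "duration_mannwhitney_p" not in st
        assert "skipped" in st["duration_comparison"]
        assert st["cytolytic_fraction"] == 0.0

    def test_fraction_of_nk_with_contact(self):
        st = nk.interaction_stats(self._eps([5.0, 6.0], OUTCOME_NONCYTOLYTIC),
                                  n_nk=10)
        assert st["fraction_nk_with_contact"] == pytest.approx(0.2)


class TestNearestTargetDistance:
    def test_single_target(self):
        nks = [_static([0, 0, 0], 3, 0, "NK")]
        tgs = [_static([30, 0, 0], 3, 1, "target")]
        df = nk.nearest_target_distance(nks, tgs)
        assert df["nearest_target_um"].iloc[0] == pytest.approx(30.0)

    def test_coincident_is_zero(self):
        nks = [_static([5, 5, 5], 3, 0, "NK")]
        tgs = [_static([5, 5, 5], 3, 1, "target")]
        assert nk.nearest_target_distance(nks, tgs)["nearest_target_um"].iloc[0] == 0.0

    def test_random_scene_matches_exhaustive_min(self):
        rng = np.random.default_rng(31)
        nks = [_static(rng.uniform(0, 100, 3), 3, i, "NK") for i in range(6)]
        tgs = [_static(rng.uniform(0, 100, 3), 3, 10 + j, "target") for j in range(4)]
        df = nk.nearest_target_distance(nks, tgs).set_index("nk_id")
        for a in nks:
            expect = min(np.linalg.norm(a.pos[0] - b.pos[0]) for b in tgs)
            assert df.loc[a.cell_id, "nearest_target_um"] == pytest.approx(expect)

    def test_no_targets_rejected(self):
        with pytest.raises(ValueError, match="no target"):
            nk.nearest_target_distance([_static([0, 0, 0], 3, 0, "NK")], [])


def test_cytolytic_assignment_recovers_ground_truth_pairs():
    """>= 95% of true (killer, target) pairs recovered when the kill delay
    is well inside the attribution window."""
    true_pairs, found_pairs = set(), set()
    for seed in range(6):
        sim = SimulationConfig(n_nk=20, n_target=10, kill_delay_mean=8.0,
                               seed=100 + seed)
        tracks, truth = nk.simulate_tracks(sim)
        ana = []
        for tr in tracks:
            alive = truth.alive.get(tr.cell_id)
            if alive is not None and not alive.all():
                n = int(alive.sum())
                if n < 2:
                    continue
                tr = Track(tr.cell_id, tr.cell_type, tr.t[:n], tr.pos[:n],
                           tr.frames[:n])
            ana.append(tr)
        nks = [t for t in ana if t.cell_type == "NK"]
        tgs = [t for t in ana if t.cell_type == "target"]
        cfg = ContactConfig()
        eps = nk.detect_contacts(nks, tgs, cfg)
        deaths = [DeathEvent(int(r.target_id), float(r.death_frame) * sim.dt)
                  for r in truth.kills.itertuples()]
        eps, _, _ = nk.assign_outcomes(eps, deaths, cfg,
                                       run_end_min=sim.duration)
        true_pairs |= {(seed, int(r.killer_id), int(r.target_id))
                       for r in truth.kills.itertuples()}
        found_pairs |= {(seed, e.nk_id, e.target_id) for e in eps
                        if e.outcome == OUTCOME_CYTOLYTIC}
    assert len(true_pairs) >= 10
    recovered = len(true_pairs & found_pairs) / len(true_pairs)
    assert recovered >= 0.95


def test_episode_dataframe_round_trip():
    eps = [nk.ContactEpisode(0, 5, 2, 4, 4.0, 10.0, 6.0)]
    df = episodes_to_dataframe(eps)
    assert list(df["outcome"]) == ["unresolved"]
    assert episodes_to_dataframe([]).empty
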