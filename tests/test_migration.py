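"""Migration analysis: filters, speed, confinement, MSD, windowed profiles,
mode classification and population summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nkwell3d as nk
from nkwell3d.config import (
    MODE_DIRECTED,
    MODE_RANDOM,
    MODE_TMAP,
    SimulationConfig,
    TrackFilterConfig,
    WindowConfig,
)
from nkwell3d.tracks import Track

from conftest import straight_track


def _track(positions, dt=2.0, cell_id=0):
    pos = np.asarray(positions, float)
    return Track(cell_id, "NK", np.arange(len(pos)) * dt, pos)


# --- filtering -------------------------------------------------------------


class TestFilterTracks:
    def test_short_track_excluded(self):
        cfg = TrackFilterConfig()
        tr = straight_track(v=1.0, n=30, dt=59.0 / 29)  # 59 min duration
        assert nk.filter_tracks([tr], cfg) == []
        tr60 = straight_track(v=1.0, n=31, dt=2.0)  # exactly 60 min
        assert nk.filter_tracks([tr60], cfg) == [tr60]

    def test_z_jump_rule_is_strict(self):
        cfg = TrackFilterConfig()
        base = np.zeros((31, 3))
        jump41 = base.copy()
        jump41[16:, 2] = 41.0
        jump40 = base.copy()
        jump40[16:, 2] = 40.0
        assert nk.filter_tracks([_track(jump41)], cfg) == []
        assert len(nk.filter_tracks([_track(jump40)], cfg)) == 1

    def test_mixed_cohort_counts(self):
        cfg = TrackFilterConfig()
        good = [straight_track(n=31, cell_id=i) for i in range(7)]
        bad_short = [straight_track(n=10, cell_id=7)]
        bad_jump = []
        for i in (8, 9):
            pos = np.zeros((31, 3))
            pos[5:, 2] = 50.0
            bad_jump.append(_track(pos, cell_id=i))
        kept = nk.filter_tracks(good + bad_short + bad_jump, cfg)
        assert [t.cell_id for t in kept] == [0, 1, 2, 3, 4, 5, 6]

    def test_filter_is_idempotent(self):
        rng = np.random.default_rng(0)
        cfg = TrackFilterConfig()
        tracks = [
            _track(np.cumsum(rng.normal(0, 15, (rng.integers(5, 60), 3)), axis=0),
                   cell_id=i)
            for i in range(20)
        ]
        once = nk.filter_tracks(tracks, cfg)
        assert nk.filter_tracks(once, cfg) == once


# --- speed and confinement -------------------------------------------------


def test_mean_speed_closed_forms():
    assert nk.mean_speed(_track(np.zeros((10, 3)))) == 0.0
    # straight steps of 6.4 um at dt = 2 min -> 3.2 um/min
    assert nk.mean_speed(straight_track(v=3.2, n=20, dt=2.0)) == pytest.approx(3.2)
    # hand-computed: steps of 5 and 12 um over 2 min each
    tr = _track([(0, 0, 0), (3, 4, 0), (3, 4, 12)])
    assert nk.mean_speed(tr) == pytest.approx(4.25)


def test_corrected_displacement_closed_forms():
    # straight line, duration 4 min: ratio 1, sqrt(4) = 2
    tr = _track([(0, 0, 0), (5, 0, 0), (10, 0, 0)])
    assert nk.corrected_displacement(tr) == pytest.approx(2.0)
    # closed loop
    loop = _track([(0, 0, 0), (5, 0, 0), (0, 0, 0)])
    assert nk.corrected_displacement(loop) == 0.0
    # hand-computed: net 13, path 17, t_tot 4
    tr2 = _track([(0, 0, 0), (3, 4, 0), (3, 4, 12)])
    assert nk.corrected_displacement(tr2) == pytest.approx(13 / 17 * 2.0)
    with pytest.raises(ValueError, match="path length"):
        nk.corrected_displacement(_track(np.zeros((3, 3))))


@given(st.integers(0, 10_000))
@settings(max_examples=30, deadline=None)
def test_corrected_displacement_bounded_by_sqrt_duration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 40))
    tr = _track(np.cumsum(rng.normal(0, 3, (n, 3)), axis=0))
    cd = nk.corrected_displacement(tr)
    assert 0.0 <= cd <= np.sqrt(tr.t_tot) + 1e-9


# --- MSD -------------------------------------------------------------------


def _msd_naive(seg, max_lag):
    seg = np.asarray(seg, float)
    out = []
    for n in range(1, max_lag + 1):
        acc = 0.0
        for i in range(len(seg) - n):
            acc += np.sum((seg[i + n] - seg[i]) ** 2)
        out.append(acc / (len(seg) - n))
    return np.array(out)


def test_msd_closed_forms():
    assert np.allclose(nk.msd(np.zeros((10, 3)), 4), 0.0)
    # ballistic: constant step d along a line -> MSD(n) = (n d)^2
    d = 2.5
    seg = np.outer(np.arange(12) * d, [1.0, 0.0, 0.0])
    np.testing.assert_allclose(nk.msd(seg, 6), (np.arange(1, 7) * d) ** 2)
    # staircase (0,0,0),(1,0,0),(1,1,0),(1,1,1) -> 1, 2, 3
    stair = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)]
    np.testing.assert_allclose(nk.msd(np.array(stair, float), 3), [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        nk.msd(np.zeros((4, 3)), 4)


def test_msd_matches_naive_double_loop():
    """Vectorized MSD equals the brute-force oracle to 1e-12."""
    rng = np.random.default_rng(5)
    for _ in range(100):
        n = int(rng.integers(8, 51))
        seg = np.cumsum(rng.normal(0, 2, (n, 3)), axis=0)
        lag = int(rng.integers(1, min(7, n)))
        np.testing.assert_allclose(nk.msd(seg, lag), _msd_naive(seg, lag),
                                   rtol=0, atol=1e-12)


# --- windowed profiles -----------------------------------------------------


def test_ballistic_window_alpha_is_two():
    tr = straight_track(v=3.0, n=40, dt=2.0)
    prof = nk.windowed_profiles(tr, WindowConfig())
    core = prof["alpha"].dropna()
    assert len(core) == 40 - 24
    assert np.all(np.abs(core - 2.0) < 1e-9)
    # edges carry no values
    assert prof["M"].isna().to_numpy()[:12].all()
    assert prof["M"].isna().to_numpy()[-12:].all()


def test_fit_msd_exact_on_linear_msd():
    """A window whose MSD is exactly n um^2 at t_n = n min fits alpha = 1
    and M = 1/6."""
    M, alpha = nk.fit_msd(np.arange(1.0, 7.0), dt=1.0)
    assert alpha == pytest.approx(1.0, abs=1e-12)
    assert M == pytest.approx(1.0 / 6.0, abs=1e-12)


def test_fit_msd_handles_zero_values():
    M, alpha = nk.fit_msd(np.zeros(6))
    assert M == 0.0 and np.isnan(alpha)


def test_windowed_M_recovers_brownian_coefficient():
    """Median windowed M within 20% of truth; median alpha in [0.8, 1.2]."""
    cfg = SimulationConfig(n_nk=30, n_target=0, mode_set=("TMAP",),
                           M_tmap=3.0, seed=21)
    tracks, _ = nk.simulate_tracks(cfg)
    wc = WindowConfig()
    Ms, alphas = [], []
    for tr in tracks:
        prof = nk.windowed_profiles(tr, wc)
        Ms.append(prof["M"].dropna())
        alphas.append(prof["alpha"].dropna())
    Ms = pd.concat(Ms)
    alphas = pd.concat(alphas)
    assert len(Ms) >= 200
    assert Ms.median() == pytest.approx(3.0, rel=0.20)
    assert 0.8 <= alphas.median() <= 1.2


def test_track_shorter_than_window_rejected():
    with pytest.raises(ValueError, match="window"):
        nk.windowed_profiles(straight_track(n=10), WindowConfig())


# --- classification --------------------------------------------------------


def _profile(M, alpha):
    n = len(M)
    return pd.DataFrame(
        {
            "frame": np.arange(n),
            "t_min": np.arange(n) * 2.0,
            "M": M,
            "alpha": alpha,
            "M_smooth": M,
            "alpha_smooth": alpha,
        }
    )


class TestClassifyModes:
    def test_low_M_is_all_tmap(self):
        prof = _profile(np.ones(30), np.ones(30))
        assert (nk.classify_modes(prof, WindowConfig()) == MODE_TMAP).all()

    def test_moderate_M_low_alpha_is_random(self):
        prof = _profile(np.full(30, 10.0), np.full(30, 1.0))
        assert (nk.classify_modes(prof, WindowConfig()) == MODE_RANDOM).all()

    def test_directed_requires_minimum_run(self):
        cfg = WindowConfig()
        for run, expected in ((9, MODE_RANDOM), (10, MODE_DIRECTED)):
            alpha = np.full(30, 1.0)
            alpha[5:5 + run] = 1.6
            modes = nk.classify_modes(_profile(np.full(30, 10.0), alpha), cfg)
            assert (modes[5:5 + run] == expected).all()

    def test_arrest_takes_precedence_over_directed(self):
        M = np.full(30, 1.0)  # below threshold everywhere
        alpha = np.full(30, 1.9)  # directed criterion also fires
        modes = nk.classify_modes(_profile(M, alpha), WindowConfig())
        assert (modes == MODE_TMAP).all()


def test_classification_recovers_switching_ground_truth(switching_cohort):
    """>= 75% frame agreement on default mode-switching tracks."""
    sim, tracks, truth = switching_cohort
    wc = WindowConfig()
    agree = total = 0
    for tr in tracks:
        labels = nk.analyze_track(tr, wc)["mode"].to_numpy()
        mask = np.array([l is not None for l in labels])
        agree += int(np.sum(labels[mask] == truth.modes[tr.cell_id][mask]))
        total += int(mask.sum())
    assert total > 5000
    assert agree / total >= 0.75


# --- Brownian threshold ----------------------------------------------------


def test_brownian_threshold_matches_printed_value():
    """Cell-sized particle in water at 37 C: 4.9 um^2/min to 2 s.f."""
    val = nk.brownian_threshold(8.0)
    assert round(val, 1) == 4.9


def test_brownian_threshold_scales_inversely_with_diameter():
    assert nk.brownian_threshold(16.0) == pytest.approx(nk.brownian_threshold(8.0) / 2)


def test_brownian_threshold_general_case():
    # 2 um bead at 20 C in water: ~0.215 um^2/s = 12.9 um^2/min
    assert nk.brownian_threshold(2.0, 293.0, 1.0e-3) == pytest.approx(12.9, rel=0.01)
    with pytest.raises(ValueError):
        nk.brownian_threshold(-1.0)


# --- summaries -------------------------------------------------------------


def _labels(seq):
    return pd.Series(list(seq), dtype=object)


def test_all_tmap_track_summary():
    tr = straight_track(n=61, dt=2.0)
    labels = _labels([MODE_TMAP] * 61)
    s = nk.summarize_track(tr, labels)
    assert s.frac_tmap == 1.0 and s.tmap_group == "high"
    assert s.transitions_per_h == 0.0


def test_single_transition_rate():
    tr = straight_track(n=61, dt=2.0)  # 120 min labelled span
    labels = _labels([MODE_RANDOM] * 30 + [MODE_DIRECTED] * 31)
    s = nk.summarize_track(tr, labels)
    assert s.transitions_per_h == pytest.approx(1 / 2.0)


def test_constructed_runs_match_brute_force_counts():
    rng = np.random.default_rng(17)
    seq = rng.choice([MODE_TMAP, MODE_RANDOM, MODE_DIRECTED], size=101)
    tr = straight_track(n=101, dt=2.0)
    s = nk.summarize_track(tr, _labels(seq))
    assert s.frac_tmap == pytest.approx(np.mean(seq == MODE_TMAP))
    assert s.frac_random == pytest.approx(np.mean(seq == MODE_RANDOM))
    switches = sum(a != b for a, b in zip(seq[:-1], seq[1:]))
    assert s.transitions_per_h == pytest.approx(switches / (100 * 2.0 / 60))
    assert abs(s.frac_tmap + s.frac_random + s.frac_directed - 1.0) < 1e-9


def test_population_summary_pooling():
    tr = straight_track(n=61, dt=2.0)
    s_rand = nk.summarize_track(tr, _labels([MODE_RANDOM] * 61))
    pop = nk.population_summary([s_rand])
    assert pop["mode_fractions"] == {MODE_TMAP: 0.0, MODE_RANDOM: 1.0,
                                     MODE_DIRECTED: 0.0}
    s_tmap = nk.summarize_track(tr, _labels([MODE_TMAP] * 61))
    s_dir = nk.summarize_track(tr, _labels([MODE_DIRECTED] * 61))
    pop2 = nk.population_summary([s_tmap, s_dir])
    assert pop2["mode_fractions"][MODE_TMAP] == pytest.approx(0.5)
    assert pop2["mode_fractions"][MODE_DIRECTED] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        nk.population_summary([])


def test_pooled_fractions_recover_generator_occupancy(switching_cohort):
    """Classified pooled mode fractions track the generator's occupancy."""
    sim, tracks, truth = switching_cohort
    wc = WindowConfig()
    summaries = []
    true_counts = {MODE_TMAP: 0, MODE_RANDOM: 0, MODE_DIRECTED: 0}
    n_lab = 0
    for tr in tracks:
        prof = nk.analyze_track(tr, wc)
        summaries.append(nk.summarize_track(tr, prof["mode"]))
        mask = prof["mode"].notna().to_numpy()
        tl = truth.modes[tr.cell_id][mask]
        for m in true_counts:
            true_counts[m] += int(np.sum(tl == m))
        n_lab += int(mask.sum())
    pop = nk.population_summary(summaries)
    for m in true_counts:
        assert pop["mode_fractions"][m] == pytest.approx(true_counts[m] / n_lab,
                                                         abs=0.10)
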