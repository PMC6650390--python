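"""Track-level migration analysis: filtering, speed, confinement, rolling-
window MSD profiles and migration-mode classification.

The central quantities are the mean-squared displacement over a 25-point
window centred on each time point,

    MSD(t_n) = 1/(N-n) * sum_i |r_{i+n} - r_i|^2 ,     t_n = n * dt,

the motility coefficient M from the 3D random-walk relation MSD = 6 M t
(slope of a linear fit to the first 6 MSD lags, divided by 6), and the
anomalous exponent alpha from the log-log slope over the same lags
(MSD ~ t^alpha: ~1 diffusive, 2 ballistic).  Windows with M below the
Brownian threshold for a cell-sized particle (4.9 um^2/min) are transient
migration arrest periods (TMAPs); sustained alpha above 1.5 marks directed
migration; everything else is random movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import (
    MODE_DIRECTED,
    MODE_RANDOM,
    MODE_TMAP,
    TrackFilterConfig,
    WindowConfig,
)
from .tracks import Track

BOLTZMANN_J_PER_K = 1.380649e-23
#: dynamic viscosity of water at 37 C, Pa s
WATER_VISCOSITY_37C = 6.9e-4
BODY_TEMPERATURE_K = 310.15


def filter_tracks(tracks: Sequence[Track], cfg: TrackFilterConfig) -> List[Track]:
    """Drop tracks shorter than ``min_duration`` or with any consecutive z
    displacement strictly greater than ``max_z_jump`` (likely linking errors
    across optical sections).  Order is preserved; the filter is idempotent.
    """
    out = []
    for tr in tracks:
        if tr.t_tot < cfg.min_duration:
            continue
        dz = np.abs(np.diff(tr.pos[:, 2]))
        if dz.size and dz.max() > cfg.max_z_jump:
            continue
        out.append(tr)
    return out


def mean_speed(track: Track) -> float:
    """Mean of consecutive-step displacements divided by the frame interval
    (um/min)."""
    if len(track) < 2:
        raise ValueError("need at least 2 points")
    return float(track.step_lengths.mean() / track.dt)


def corrected_displacement(track: Track) -> float:
    """Confinement index: net over total displacement, scaled by sqrt(track
    duration) — ||r_end - r_1|| / d_tot * sqrt(t_tot), in sqrt(min).

    Low values indicate confined cells; a straight path of duration T gives
    sqrt(T).
    """
    d_tot = track.d_tot
    if d_tot <= 0:
        raise ValueError("zero total path length; confinement undefined")
    net = float(np.linalg.norm(track.r_end - track.r_1))
    return net / d_tot * float(np.sqrt(track.t_tot))


def msd(segment: np.ndarray, max_lag: int, dt: float = 1.0) -> np.ndarray:
    """Time-averaged 3D MSD of a position segment for lags 1..max_lag.

    Parameters
    ----------
    segment : ndarray (N, 3) of consecutive positions, N > max_lag.
    dt : frame interval; only used by callers to form t_n = n*dt.

    Returns
    -------
    ndarray (max_lag,) with MSD(t_n) in um^2.
    """
    segment = np.asarray(segment, dtype=float)
    n_pts = segment.shape[0]
    if max_lag >= n_pts:
        raise ValueError("max_lag must be smaller than the segment length")
    out = np.empty(max_lag)
    for n in range(1, max_lag + 1):
        d = segment[n:] - segment[:-n]
        out[n - 1] = np.mean(np.sum(d * d, axis=1))
    return out


def _window_msds(pos: np.ndarray, window: int, max_lag: int) -> np.ndarray:
    """MSD lags 1..max_lag for every centred window, vectorized.

    Returns (n_windows, max_lag); window c covers pos[c : c+window].
    """
    from numpy.lib.stride_tricks import sliding_window_view

    w = sliding_window_view(pos, (window, 3)).squeeze(axis=1)  # (n_win, window, 3)
    n_win = w.shape[0]
    out = np.empty((n_win, max_lag))
    for n in range(1, max_lag + 1):
        d = w[:, n:, :] - w[:, :-n, :]
        out[:, n - 1] = np.mean(np.sum(d * d, axis=2), axis=1)
    return out


def fit_msd(msd_values: np.ndarray, dt: float = 1.0) -> Tuple[float, float]:
    """Fit one window's MSD curve: returns (M, alpha).

    M is the slope of an unconstrained linear fit of MSD vs t over the
    supplied lags, divided by 6 (clipped at 0); alpha is the slope of the
    log-log fit over the same lags (NaN when any MSD value is 0).  This is
    the per-window computation behind :func:`windowed_profiles`.
    """
    msd_values = np.asarray(msd_values, dtype=float)
    lags = np.arange(1, msd_values.size + 1) * dt
    A = np.column_stack([lags, np.ones_like(lags)])
    slope = np.linalg.lstsq(A, msd_values, rcond=None)[0][0]
    M = max(slope / 6.0, 0.0)
    if (msd_values <= 0).any():
        return M, float("nan")
    Alog = np.column_stack([np.log(lags), np.ones_like(lags)])
    alpha = np.linalg.lstsq(Alog, np.log(msd_values), rcond=None)[0][0]
    return M, float(alpha)


def _rolling_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centred rolling average, NaN-aware, shrinking at the edges."""
    return (
        pd.Series(x)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def windowed_profiles(track: Track, cfg: WindowConfig) -> pd.DataFrame:
    """Rolling-window M and alpha profiles of one track.

    For each time point with a full centred window of ``cfg.window`` points,
    the window MSD is fitted twice over lags 1..fit_points: an unconstrained
    linear fit of MSD vs t whose slope/6 gives M (clipped at 0), and a
    linear fit of log MSD vs log t whose slope gives alpha (NaN when any
    MSD lag is exactly zero).  Both profiles are then smoothed by a centred
    rolling average of ``smooth_window`` points.

    Returns a DataFrame indexed like the track with columns
    ``frame, t_min, M, alpha, M_smooth, alpha_smooth``; points within half
    a window of either end carry NaN and receive no mode label downstream.
    """
    n_pts = len(track)
    if n_pts < cfg.window:
        raise ValueError(f"track has {n_pts} points; need >= window ({cfg.window})")
    half = cfg.half_window
    dt = track.dt
    lags = np.arange(1, cfg.fit_points + 1) * dt

    msds = _window_msds(track.pos, cfg.window, cfg.fit_points)  # (n_win, fit_points)
    n_win = msds.shape[0]

    # linear fit with intercept, shared design matrix
    A = np.column_stack([lags, np.ones_like(lags)])
    pinv = np.linalg.pinv(A)
    slopes = pinv[0] @ msds.T
    M = np.clip(slopes / 6.0, 0.0, None)

    alpha = np.full(n_win, np.nan)
    ok = (msds > 0).all(axis=1)
    if ok.any():
        Alog = np.column_stack([np.log(lags), np.ones_like(lags)])
        pinv_log = np.linalg.pinv(Alog)
        alpha[ok] = pinv_log[0] @ np.log(msds[ok]).T

    M_full = np.full(n_pts, np.nan)
    a_full = np.full(n_pts, np.nan)
    centers = np.arange(half, half + n_win)
    M_full[centers] = M
    a_full[centers] = alpha

    prof = pd.DataFrame(
        {
            "frame": track.frames,
            "t_min": track.t,
            "M": M_full,
            "alpha": a_full,
        }
    )
    # smooth only over the labelled core, keeping the edge NaNs
    M_s = np.full(n_pts, np.nan)
    a_s = np.full(n_pts, np.nan)
    M_s[centers] = _rolling_mean(M, cfg.smooth_window)
    a_s[centers] = _rolling_mean(alpha, cfg.smooth_window)
    prof["M_smooth"] = M_s
    prof["alpha_smooth"] = a_s
    return prof


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of maximal True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for s, e in zip(idx[::2], idx[1::2]):
        yield int(s), int(e)


def classify_modes(profile: pd.DataFrame, cfg: WindowConfig) -> pd.Series:
    """Assign TMAP / directed / random labels from smoothed profiles.

    Arrest takes precedence: any point with smoothed M below ``M_threshold``
    is TMAP.  Directed migration requires smoothed alpha above
    ``alpha_threshold`` for at least ``directed_min_run`` consecutive
    profiled points, and applies only outside arrest.  Remaining profiled
    points are random movement; unprofiled points stay unlabelled (None).
    """
    M_s = profile["M_smooth"].to_numpy()
    a_s = profile["alpha_smooth"].to_numpy()
    labeled = ~np.isnan(M_s)
    tmap = labeled & (M_s < cfg.M_threshold)
    cand = np.zeros_like(tmap)
    with np.errstate(invalid="ignore"):
        raw = a_s > cfg.alpha_threshold  # NaN alpha -> not directed
    for s, e in _runs(raw & labeled):
        if e - s >= cfg.directed_min_run:
            cand[s:e] = True
    directed = cand & ~tmap
    modes = np.where(tmap, MODE_TMAP, np.where(directed, MODE_DIRECTED, MODE_RANDOM))
    out = pd.Series(modes, index=profile.index, dtype=object)
    out[~labeled] = None
    return out


def analyze_track(track: Track, cfg: WindowConfig) -> pd.DataFrame:
    """Convenience: windowed profiles plus a ``mode`` column."""
    prof = windowed_profiles(track, cfg)
    prof["mode"] = classify_modes(prof, cfg)
    return prof


def brownian_threshold(
    diameter_um: float = 8.0,
    temperature_K: float = BODY_TEMPERATURE_K,
    viscosity_Pa_s: float = WATER_VISCOSITY_37C,
) -> float:
    """Stokes-Einstein diffusion coefficient of a sphere, in um^2/min.

    D = k_B T / (6 pi eta r).  For a cell-sized particle (8 um diameter) in
    water at 37 C this gives ~4.9 um^2/min, the motility-coefficient
    threshold separating migration arrest from active movement.
    """
    if diameter_um <= 0 or temperature_K <= 0 or viscosity_Pa_s <= 0:
        raise ValueError("all inputs must be > 0")
    r_m = diameter_um * 1e-6 / 2.0
    D_m2_s = BOLTZMANN_J_PER_K * temperature_K / (6.0 * np.pi * viscosity_Pa_s * r_m)
    return D_m2_s * 1e12 * 60.0  # m^2/s -> um^2/min


@dataclass
class TrackSummary:
    """Per-track migration summary."""

    cell_id: int
    mean_speed: float
    corrected_displacement: float
    frac_tmap: float
    frac_random: float
    frac_directed: float
    transitions_per_h: float
    tmap_group: str
    labeled_duration_min: float
    n_labeled: int
    dwell_times_min: List[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "cell_id", "mean_speed", "corrected_displacement", "frac_tmap",
            "frac_random", "frac_directed", "transitions_per_h", "tmap_group",
            "labeled_duration_min", "n_labeled")}
        return d


def _tmap_group(frac: float) -> str:
    if frac < 0.10:
        return "low"
    if frac > 0.90:
        return "high"
    return "medium"


def summarize_track(track: Track, labels: pd.Series) -> TrackSummary:
    """Mode fractions, switching rate and TMAP group of one labelled track.

    ``labels`` is the per-point mode series from :func:`classify_modes`;
    unlabelled window-edge points are excluded from all denominators.
    Transitions per hour use the labelled span ((n-1) * dt).  Dwell times
    are durations of interior label runs (bounded by a switch on both
    sides), i.e. completed mode visits.
    """
    lab = labels.dropna()
    if lab.empty:
        raise ValueError("track has no labelled points")
    vals = lab.to_numpy()
    n = vals.size
    dt = track.dt
    fracs = {m: float(np.mean(vals == m)) for m in (MODE_TMAP, MODE_RANDOM, MODE_DIRECTED)}
    switches = int(np.sum(vals[1:] != vals[:-1]))
    span_min = (n - 1) * dt
    per_h = switches / (span_min / 60.0) if span_min > 0 else 0.0

    # interior (completed) run durations
    dwells: List[float] = []
    if switches >= 2:
        change = np.flatnonzero(vals[1:] != vals[:-1]) + 1
        for s, e in zip(change[:-1], change[1:]):
            dwells.append(float((e - s) * dt))

    return TrackSummary(
        cell_id=track.cell_id,
        mean_speed=mean_speed(track),
        corrected_displacement=corrected_displacement(track),
        frac_tmap=fracs[MODE_TMAP],
        frac_random=fracs[MODE_RANDOM],
        frac_directed=fracs[MODE_DIRECTED],
        transitions_per_h=per_h,
        tmap_group=_tmap_group(fracs[MODE_TMAP]),
        labeled_duration_min=span_min,
        n_labeled=n,
        dwell_times_min=dwells,
    )


def population_summary(summaries: Sequence[TrackSummary]) -> dict:
    """Pool per-track summaries into population statistics.

    Mode fractions are time-weighted by each track's labelled point count;
    speed and confinement are reported as mean, SD (ddof=1) and the raw
    per-track values; the dwell mean pools completed mode visits.
    """
    if not summaries:
        raise ValueError("no track summaries supplied")
    w = np.array([s.n_labeled for s in summaries], dtype=float)
    w = w / w.sum()
    fr = {
        m: float(np.sum(w * np.array([getattr(s, f"frac_{k}") for s in summaries])))
        for m, k in ((MODE_TMAP, "tmap"), (MODE_RANDOM, "random"), (MODE_DIRECTED, "directed"))
    }
    speeds = np.array([s.mean_speed for s in summaries])
    conf = np.array([s.corrected_displacement for s in summaries])
    trans = np.array([s.transitions_per_h for s in summaries])
    dwells = [d for s in summaries for d in s.dwell_times_min]
    groups = pd.Series([s.tmap_group for s in summaries]).value_counts().to_dict()
    return {
        "n_tracks": len(summaries),
        "mode_fractions": fr,
        "mean_speed": float(speeds.mean()),
        "sd_speed": float(speeds.std(ddof=1)) if len(speeds) > 1 else 0.0,
        "speeds": speeds.tolist(),
        "mean_corrected_displacement": float(conf.mean()),
        "corrected_displacements": conf.tolist(),
        "transitions_per_h": trans.tolist(),
        "mean_transitions_per_h": float(trans.mean()),
        "mean_dwell_min": float(np.mean(dwells)) if dwells else float("nan"),
        "n_completed_dwells": len(dwells),
        "tmap_groups": {k: int(v) for k, v in groups.items()},
    }
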