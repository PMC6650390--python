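"""NK-target interaction analysis: contact episodes, death calls from
fluorescence loss, cytolytic outcome assignment and summary statistics.

A contact (conjugation) is a maximal run of frames in which an NK-target
pair sits at a centre-to-centre distance strictly below the contact radius
(20 um by default).  Target death shows up as sustained loss of calcein
fluorescence; an episode is cytolytic when its target dies during the
episode or within the attribution window after it ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import ContactConfig
from .tracks import Track

OUTCOME_CYTOLYTIC = "cytolytic"
OUTCOME_NONCYTOLYTIC = "non-cytolytic"
OUTCOME_UNRESOLVED = "unresolved"


@dataclass
class ContactEpisode:
    """One NK-target conjugation interval.

    ``start_min`` is the time of the first in-contact frame; the duration is
    ``n_frames * dt`` (a single-frame episode lasts one frame interval) and
    ``end_min = start_min + duration_min``.
    """

    nk_id: int
    target_id: int
    start_frame: int
    end_frame: int  # inclusive
    start_min: float
    end_min: float
    duration_min: float
    outcome: str = OUTCOME_UNRESOLVED

    def as_dict(self) -> dict:
        return {
            "nk_id": self.nk_id,
            "target_id": self.target_id,
            "start_frame": self.start_frame,
            "end_frame": self.end_frame,
            "start_min": self.start_min,
            "end_min": self.end_min,
            "duration_min": self.duration_min,
            "outcome": self.outcome,
        }


@dataclass
class DeathEvent:
    target_id: int
    death_min: float
    source: str = "ground-truth"  # or "intensity-called", "manual"


def episodes_to_dataframe(episodes: Sequence[ContactEpisode]) -> pd.DataFrame:
    cols = ["nk_id", "target_id", "start_frame", "end_frame",
            "start_min", "end_min", "duration_min", "outcome"]
    if not episodes:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([e.as_dict() for e in episodes])[cols]


def detect_contacts(
    nk_tracks: Sequence[Track],
    target_tracks: Sequence[Track],
    cfg: ContactConfig,
) -> List[ContactEpisode]:
    """Find all NK-target contact episodes.

    For every pair, frames present in both tracks with Euclidean distance
    strictly below ``contact_radius`` form episodes; runs separated by at
    most ``gap_tolerance`` non-contact or missing frames are merged.
    Episodes are returned sorted by (nk_id, target_id, start_frame).
    """
    episodes: List[ContactEpisode] = []
    for nk in nk_tracks:
        nk_map = {int(f): nk.pos[i] for i, f in enumerate(nk.frames)}
        dt = nk.dt
        for tg in target_tracks:
            frames = sorted(set(nk_map) & {int(f) for f in tg.frames})
            if not frames:
                continue
            tg_map = {int(f): tg.pos[i] for i, f in enumerate(tg.frames)}
            contact_frames = [
                f for f in frames
                if np.linalg.norm(nk_map[f] - tg_map[f]) < cfg.contact_radius
            ]
            if not contact_frames:
                continue
            runs: List[List[int]] = [[contact_frames[0], contact_frames[0]]]
            for f in contact_frames[1:]:
                if f - runs[-1][1] <= cfg.gap_tolerance + 1:
                    runs[-1][1] = f
                else:
                    runs.append([f, f])
            for s, e in runs:
                n_frames = e - s + 1
                t0 = s * dt
                episodes.append(
                    ContactEpisode(
                        nk_id=nk.cell_id,
                        target_id=tg.cell_id,
                        start_frame=s,
                        end_frame=e,
                        start_min=t0,
                        end_min=t0 + n_frames * dt,
                        duration_min=n_frames * dt,
                    )
                )
    episodes.sort(key=lambda e: (e.nk_id, e.target_id, e.start_frame))
    return episodes


def detect_target_death(
    intensity: np.ndarray,
    cfg: ContactConfig,
    dt: float,
    target_id: int = -1,
) -> Optional[DeathEvent]:
    """Call target death from a per-frame total-intensity trace.

    Death is called at the first frame whose intensity falls below
    ``death_intensity_fraction`` of the running pre-drop baseline (mean of
    all earlier frames) and stays below it for at least
    ``death_min_frames`` consecutive frames; transient dips are ignored.
    Returns ``None`` for a target that never loses fluorescence.
    """
    trace = np.asarray(intensity, dtype=float)
    if trace.size < cfg.death_min_frames:
        raise ValueError("trace shorter than death_min_frames")
    for f in range(1, trace.size - cfg.death_min_frames + 1):
        baseline = trace[:f].mean()
        if baseline <= 0:
            continue
        seg = trace[f:f + cfg.death_min_frames]
        if np.all(seg < cfg.death_intensity_fraction * baseline):
            return DeathEvent(target_id=target_id, death_min=f * dt,
                              source="intensity-called")
    return None


def assign_outcomes(
    episodes: Sequence[ContactEpisode],
    deaths: Sequence[DeathEvent],
    cfg: ContactConfig,
    run_end_min: Optional[float] = None,
) -> Tuple[List[ContactEpisode], pd.DataFrame, List[DeathEvent]]:
    """Attribute target deaths to contact episodes and tally per-NK counts.

    An episode qualifies for a death if the death time lies within
    [start, end + death_attribution_window].  Among qualifying episodes the
    one overlapping the death instant wins (latest start breaking ties);
    otherwise the one whose end most closely precedes the death.  Episodes
    still open at ``run_end_min`` with no attributed death stay unresolved;
    every other non-winning episode is non-cytolytic.

    Returns (episodes with outcome, per-NK tally table, unattributed deaths).
    """
    episodes = list(episodes)
    for e in episodes:
        e.outcome = OUTCOME_NONCYTOLYTIC
        if run_end_min is not None and e.end_min >= run_end_min - 1e-9:
            e.outcome = OUTCOME_UNRESOLVED
    unattributed: List[DeathEvent] = []
    for death in deaths:
        cands = [
            e for e in episodes
            if e.target_id == death.target_id
            and e.start_min - 1e-9 <= death.death_min <= e.end_min + cfg.death_attribution_window + 1e-9
        ]
        if not cands:
            unattributed.append(death)
            continue
        overlapping = [e for e in cands if death.death_min <= e.end_min + 1e-9]
        if overlapping:
            winner = max(overlapping, key=lambda e: e.start_min)
        else:
            winner = max(cands, key=lambda e: e.end_min)
        winner.outcome = OUTCOME_CYTOLYTIC

    nk_ids = sorted({e.nk_id for e in episodes})
    rows = []
    for nk in nk_ids:
        own = [e for e in episodes if e.nk_id == nk]
        rows.append(
            {
                "nk_id": nk,
                "contacts": len(own),
                "kills": sum(e.outcome == OUTCOME_CYTOLYTIC for e in own),
            }
        )
    tallies = pd.DataFrame(rows, columns=["nk_id", "contacts", "kills"])
    return episodes, tallies, unattributed


def interaction_stats(
    episodes: Sequence[ContactEpisode],
    n_nk: Optional[int] = None,
) -> dict:
    """Population-level interaction statistics.

    Reports contact counts, mean +/- SD (ddof=1) conjugation duration, the
    cytolytic fraction among resolved episodes, and a two-sided
    Mann-Whitney U test comparing cytolytic vs non-cytolytic durations
    (skipped with a notice when either group is empty).  With ``n_nk`` the
    fraction of NK cells that made at least one contact is included.
    """
    if not episodes:
        raise ValueError("no episodes to summarize")
    durations = np.array([e.duration_min for e in episodes])
    cyto = np.array([e.duration_min for e in episodes if e.outcome == OUTCOME_CYTOLYTIC])
    noncyto = np.array([e.duration_min for e in episodes if e.outcome == OUTCOME_NONCYTOLYTIC])
    n_resolved = len(cyto) + len(noncyto)
    out = {
        "n_episodes": len(episodes),
        "n_cytolytic": int(len(cyto)),
        "n_noncytolytic": int(len(noncyto)),
        "n_unresolved": int(len(episodes) - n_resolved),
        "mean_duration_min": float(durations.mean()),
        "sd_duration_min": float(durations.std(ddof=1)) if len(durations) > 1 else 0.0,
        "cytolytic_fraction": float(len(cyto) / n_resolved) if n_resolved else float("nan"),
    }
    contacts_per_nk = pd.Series([e.nk_id for e in episodes]).value_counts()
    out["max_contacts_per_nk"] = int(contacts_per_nk.max())
    if n_nk is not None:
        out["fraction_nk_with_contact"] = float(len(contacts_per_nk) / n_nk)
    if len(cyto) and len(noncyto):
        res = stats.mannwhitneyu(cyto, noncyto, alternative="two-sided",
                                 method="exact" if (len(cyto) < 9 and len(noncyto) < 9) else "auto")
        out["duration_mannwhitney_U"] = float(res.statistic)
        out["duration_mannwhitney_p"] = float(res.pvalue)
    else:
        out["duration_comparison"] = "skipped: a group is empty"
    return out


def nearest_target_distance(
    nk_tracks: Sequence[Track],
    target_tracks: Sequence[Track],
) -> pd.DataFrame:
    """Distance from each NK cell's first position to the nearest target
    present at that frame.  Raises when there are no targets."""
    if not target_tracks:
        raise ValueError("no target tracks")
    rows = []
    for nk in nk_tracks:
        f0 = int(nk.frames[0])
        p0 = nk.pos[0]
        dists = []
        for tg in target_tracks:
            idx = np.flatnonzero(tg.frames == f0)
            if idx.size:
                dists.append(float(np.linalg.norm(tg.pos[idx[0]] - p0)))
        rows.append({"nk_id": nk.cell_id,
                     "nearest_target_um": min(dists) if dists else float("nan")})
    return pd.DataFrame(rows, columns=["nk_id", "nearest_target_um"])
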