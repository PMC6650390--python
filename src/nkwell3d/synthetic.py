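"""Synthetic assay generator: mode-switching 3D trajectories and rendered volumes.

NK cells follow a three-state continuous-time Markov process over confined
(``TMAP``), Brownian (``random``) and persistent (``directed``) motion with
exponential dwell times; target cells are slow Brownian particles.  Contacts
(centre distance below the contact radius) stochastically trigger kills;
killed targets freeze and their fluorescence is dimmed by the renderer.
Everything is reproducible from the config seed, and full ground truth
(positions, per-frame mode labels, contact intervals, kill events) is
returned for benchmarking the downstream analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import (
    ALL_MODES,
    MODE_DIRECTED,
    MODE_RANDOM,
    MODE_TMAP,
    NK,
    TARGET,
    ImageRenderConfig,
    SimulationConfig,
)
from .tracks import Track


@dataclass
class SimulationGroundTruth:
    """True state of a simulated assay run.

    Attributes
    ----------
    modes : dict cell_id -> ndarray of str
        Per-frame migration mode of each NK cell.
    alive : dict cell_id -> ndarray of bool
        Per-frame viability of each target cell (False from the death frame).
    contacts : DataFrame [nk_id, target_id, start_frame, end_frame]
        Maximal intervals with centre distance < contact_radius while the
        target was alive; end_frame inclusive.
    kills : DataFrame [target_id, death_frame, killer_id]
        At most one row per target.
    mode_intervals : DataFrame [cell_id, mode, t_start, t_end, dwell_drawn]
        The continuous-time mode schedule; ``dwell_drawn`` is the sampled
        (uncensored) dwell time of the episode, ``t_end`` is clipped to the
        run duration.
    """

    modes: Dict[int, np.ndarray] = field(default_factory=dict)
    alive: Dict[int, np.ndarray] = field(default_factory=dict)
    contacts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["nk_id", "target_id", "start_frame", "end_frame"]
        )
    )
    kills: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["target_id", "death_frame", "killer_id"])
    )
    mode_intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["cell_id", "mode", "t_start", "t_end", "dwell_drawn"]
        )
    )


def _stage_rngs(seed: int, n: int) -> List[np.random.Generator]:
    """Independent generators for the simulator's stochastic sub-processes."""
    ss = np.random.SeedSequence(int(seed))
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def _reflect(pos: np.ndarray, heading: Optional[np.ndarray], well: np.ndarray):
    """Fold positions back into [0, L] per axis, flipping headings on bounce.

    One fold per axis handles the step sizes used here (steps are far
    smaller than the well); iterate until inside for safety.
    """
    for _ in range(16):
        below = pos < 0
        above = pos > well
        if not (below.any() or above.any()):
            break
        pos = np.where(below, -pos, pos)
        pos = np.where(above, 2 * well - pos, pos)
        if heading is not None:
            flip = below | above
            heading = np.where(flip, -heading, heading)
    return pos, heading


def _sample_mode_schedule(rng: np.random.Generator, cfg: SimulationConfig):
    """Continuous-time mode schedule for one NK cell.

    Returns (episodes, per-frame mode index) where episodes is a list of
    (t_start, t_end_clipped, mode_index, dwell_drawn).
    """
    modes = list(cfg.mode_set)
    k = len(modes)
    t_end = cfg.duration
    episodes = []
    t = 0.0
    m = int(rng.integers(k)) if k > 1 else 0
    while t < t_end:
        dwell = float(rng.exponential(cfg.dwell_mean)) if k > 1 else math.inf
        episodes.append((t, min(t + dwell, t_end), m, dwell))
        t += dwell
        if k > 1:
            # jump uniformly to one of the other modes
            step = 1 + int(rng.integers(k - 1))
            m = (m + step) % k
    # frame labels: the episode covering each frame time
    n_frames = cfg.n_frames
    labels = np.empty(n_frames, dtype=object)
    ei = 0
    for i in range(n_frames):
        ti = i * cfg.dt
        while ei + 1 < len(episodes) and ti >= episodes[ei][1] - 1e-12 and ti >= episodes[ei + 1][0] - 1e-12:
            ei += 1
        labels[i] = modes[episodes[ei][2]]
    return episodes, labels


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _resolve_collisions(nk_path: np.ndarray, tg_path: np.ndarray, frame: int,
                        min_sep: float) -> None:
    """Enforce excluded volume: cells whose step lands within ``min_sep`` of
    another cell stall at their previous position for this frame.

    Cells are processed in a fixed order; a stalled cell keeps its previous
    position, which cannot create new conflicts with already-settled cells
    closer than the previous frame allowed.
    """
    n_nk = nk_path.shape[1]
    cur = np.concatenate([nk_path[frame], tg_path[frame]], axis=0)
    prev = np.concatenate([nk_path[frame - 1], tg_path[frame - 1]], axis=0)
    n = cur.shape[0]
    for c in range(n):
        others = np.delete(cur, c, axis=0)
        if others.size and np.linalg.norm(others - cur[c], axis=1).min() < min_sep:
            cur[c] = prev[c]
    nk_path[frame] = cur[:n_nk]
    tg_path[frame] = cur[n_nk:]


def simulate_tracks(cfg: SimulationConfig) -> Tuple[List[Track], SimulationGroundTruth]:
    """Simulate an assay run.

    NK steps: in ``TMAP``/``random`` mode, isotropic Gaussian displacements
    with per-axis variance ``2 M dt`` (so the 3D MSD slope is ``6 M``); in
    ``directed`` mode, ``v_directed * dt`` along a heading drawn once per
    episode.  Targets take Brownian steps with ``target_M`` until killed.
    Reflecting boundaries confine all cells to the well.

    Returns
    -------
    (tracks, truth)
        ``tracks`` lists NK tracks first (ids 0..n_nk-1) then targets
        (ids n_nk..); ``truth`` carries modes, contacts, kills and viability.
    """
    rng_modes, rng_nk, rng_tg, rng_kill, rng_init = _stage_rngs(cfg.seed, 5)
    n_frames = cfg.n_frames
    well = np.asarray(cfg.well_size, dtype=float)
    dt = cfg.dt

    truth = SimulationGroundTruth()

    # --- NK mode schedules and headings ---------------------------------
    schedules = []
    interval_rows = []
    for j in range(cfg.n_nk):
        episodes, labels = _sample_mode_schedule(rng_modes, cfg)
        headings = {}
        for idx, (t0, t1, m, dwell) in enumerate(episodes):
            if cfg.mode_set[m] == MODE_DIRECTED:
                headings[idx] = _unit_vector(rng_modes)
            interval_rows.append((j, cfg.mode_set[m], t0, t1, dwell))
        schedules.append((episodes, labels, headings))
        truth.modes[j] = labels
    truth.mode_intervals = pd.DataFrame(
        interval_rows, columns=["cell_id", "mode", "t_start", "t_end", "dwell_drawn"]
    )

    # --- initial positions: uniform with excluded volume ----------------
    n_cells = cfg.n_nk + cfg.n_target
    placed = np.empty((n_cells, 3))
    for c in range(n_cells):
        for _ in range(200):
            p = rng_init.uniform(0.0, 1.0, size=3) * well
            if c == 0 or cfg.min_separation == 0:
                break
            if np.linalg.norm(placed[:c] - p, axis=1).min() >= cfg.min_separation:
                break
        placed[c] = p
    nk_pos = placed[: cfg.n_nk]
    tg_pos = placed[cfg.n_nk:]

    nk_path = np.empty((n_frames, cfg.n_nk, 3))
    tg_path = np.empty((n_frames, cfg.n_target, 3))
    nk_path[0] = nk_pos
    tg_path[0] = tg_pos

    nk_heading = np.zeros((cfg.n_nk, 3))
    episode_idx = np.zeros(cfg.n_nk, dtype=int)

    death_frame = np.full(cfg.n_target, -1, dtype=int)  # -1: never dies
    killer = np.full(cfg.n_target, -1, dtype=int)
    doomed = np.zeros(cfg.n_target, dtype=bool)

    sigma_nk = {MODE_TMAP: math.sqrt(2 * cfg.M_tmap * dt),
                MODE_RANDOM: math.sqrt(2 * cfg.M_random * dt)}
    sigma_tg = math.sqrt(2 * cfg.target_M * dt)

    contact_open: Dict[Tuple[int, int], int] = {}  # (nk, target) -> start frame
    contact_rows = []

    def _alive_at(frame: int) -> np.ndarray:
        return (death_frame < 0) | (frame < death_frame)

    def _scan_contacts(frame: int) -> None:
        if cfg.n_nk == 0 or cfg.n_target == 0:
            return
        alive = _alive_at(frame)
        d = np.linalg.norm(nk_path[frame][:, None, :] - tg_path[frame][None, :, :], axis=2)
        in_contact = (d < cfg.contact_radius) & alive[None, :]
        for j in range(cfg.n_nk):
            for k in range(cfg.n_target):
                key = (j, k)
                if in_contact[j, k]:
                    if key not in contact_open:
                        contact_open[key] = frame
                        # a fresh conjugation may commit the target to death
                        if not doomed[k] and rng_kill.random() < cfg.p_kill_per_contact:
                            doomed[k] = True
                            delay = rng_kill.exponential(cfg.kill_delay_mean)
                            df_ = max(frame + 1, int(math.ceil((frame * dt + delay) / dt)))
                            if df_ < n_frames:
                                death_frame[k] = df_
                                killer[k] = j
                            # death beyond the run is censored: never observed
                elif key in contact_open:
                    contact_rows.append((j, k, contact_open.pop(key), frame - 1))

    _scan_contacts(0)

    for i in range(1, n_frames):
        # NK step governed by the mode active at the start of the interval
        if cfg.n_nk:
            steps = np.empty((cfg.n_nk, 3))
            for j in range(cfg.n_nk):
                episodes, labels, headings = schedules[j]
                t_prev = (i - 1) * dt
                ei = episode_idx[j]
                while ei + 1 < len(episodes) and t_prev >= episodes[ei][1] - 1e-12:
                    ei += 1
                episode_idx[j] = ei
                mode = cfg.mode_set[episodes[ei][2]]
                if mode == MODE_DIRECTED:
                    nk_heading[j] = headings[ei]
                    steps[j] = cfg.v_directed * dt * nk_heading[j]
                else:
                    steps[j] = rng_nk.normal(0.0, sigma_nk[mode], size=3)
            new_pos, new_head = _reflect(nk_path[i - 1] + steps, nk_heading, well)
            nk_path[i] = new_pos
            nk_heading = new_head
            # persist flipped headings back into the episode table
            for j in range(cfg.n_nk):
                episodes, labels, headings = schedules[j]
                ei = episode_idx[j]
                if cfg.mode_set[episodes[ei][2]] == MODE_DIRECTED:
                    headings[ei] = nk_heading[j]
        if cfg.n_target:
            alive_prev = _alive_at(i)
            steps = rng_tg.normal(0.0, sigma_tg, size=(cfg.n_target, 3))
            steps[~alive_prev] = 0.0  # dead targets freeze
            tg_path[i], _ = _reflect(tg_path[i - 1] + steps, None, well)
        if cfg.min_separation > 0 and (cfg.n_nk + cfg.n_target) > 1:
            _resolve_collisions(nk_path, tg_path, i, cfg.min_separation)
        _scan_contacts(i)

    for (j, k), start in sorted(contact_open.items()):
        contact_rows.append((j, k, start, n_frames - 1))
    truth.contacts = pd.DataFrame(
        sorted(contact_rows), columns=["nk_id", "target_id", "start_frame", "end_frame"]
    )
    kill_rows = [
        (int(k + cfg.n_nk), int(death_frame[k]), int(killer[k]))
        for k in range(cfg.n_target)
        if death_frame[k] >= 0
    ]
    truth.kills = pd.DataFrame(kill_rows, columns=["target_id", "death_frame", "killer_id"])
    # contacts/kills reference global cell ids: NK 0..n_nk-1, targets offset
    if len(truth.contacts):
        truth.contacts["target_id"] += cfg.n_nk

    t = np.arange(n_frames) * dt
    tracks: List[Track] = []
    for j in range(cfg.n_nk):
        tracks.append(Track(cell_id=j, cell_type=NK, t=t.copy(), pos=nk_path[:, j, :]))
    for k in range(cfg.n_target):
        cid = cfg.n_nk + k
        tracks.append(Track(cell_id=cid, cell_type=TARGET, t=t.copy(), pos=tg_path[:, k, :]))
        alive = np.ones(n_frames, dtype=bool)
        if death_frame[k] >= 0:
            alive[death_frame[k]:] = False
        truth.alive[cid] = alive
    return tracks, truth


# ---------------------------------------------------------------------------
# rendering


def _paint_blob(channel: np.ndarray, pos_um, sigma_um, amplitude: float,
                voxel_size) -> None:
    """Add an anisotropic Gaussian blob to a (z, y, x) stack, in place."""
    vx, vy, vz = voxel_size
    sx, sy, sz = sigma_um
    nz, ny, nx = channel.shape
    cx, cy, cz = pos_um[0] / vx, pos_um[1] / vy, pos_um[2] / vz
    rx = max(1, int(math.ceil(4 * sx / vx)))
    ry = max(1, int(math.ceil(4 * sy / vy)))
    rz = max(1, int(math.ceil(4 * sz / vz)))
    x0, x1 = max(0, int(cx) - rx), min(nx, int(cx) + rx + 2)
    y0, y1 = max(0, int(cy) - ry), min(ny, int(cy) + ry + 2)
    z0, z1 = max(0, int(cz) - rz), min(nz, int(cz) + rz + 2)
    if x0 >= x1 or y0 >= y1 or z0 >= z1:
        return
    xs = (np.arange(x0, x1) - cx) * vx
    ys = (np.arange(y0, y1) - cy) * vy
    zs = (np.arange(z0, z1) - cz) * vz
    g = (
        np.exp(-0.5 * (zs / sz) ** 2)[:, None, None]
        * np.exp(-0.5 * (ys / sy) ** 2)[None, :, None]
        * np.exp(-0.5 * (xs / sx) ** 2)[None, None, :]
    )
    channel[z0:z1, y0:y1, x0:x1] += amplitude * g


def render_volumes(
    tracks: Sequence[Track],
    truth: SimulationGroundTruth,
    rc: ImageRenderConfig,
    seed: int,
):
    """Render tracks into an 8-bit two-channel voxel time series.

    Channel 0 holds NK cells, channel 1 targets.  From its death frame on, a
    target's blob amplitude is scaled by ``post_kill_intensity_fraction``.
    Poisson noise (if ``poisson_gain`` is set) and Gaussian read noise are
    applied last; output values are clipped to [0, 255] and stored as uint8.

    Returns a :class:`~nkwell3d.volumes.VolumeSeries`.
    """
    from .volumes import VolumeSeries

    if not tracks:
        raise ValueError("cannot render an empty track set")
    n_frames = max(int(tr.frames[-1]) for tr in tracks) + 1
    dt = tracks[0].dt
    ext = rc.physical_extent
    for tr in tracks:
        if (tr.pos < -1e-9).any() or (tr.pos > np.asarray(ext) + 1e-9).any():
            raise ValueError(
                f"track {tr.cell_id} leaves the rendered extent {ext}; "
                "use a frame_shape/voxel_size covering the well"
            )

    nz, ny, nx = rc.frame_shape
    data = np.empty((n_frames, 2, nz, ny, nx), dtype=np.uint8)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))
    sigma = rc.psf_sigma

    by_frame: Dict[int, List] = {}
    for tr in tracks:
        ch = 0 if tr.cell_type == NK else 1
        alive = truth.alive.get(tr.cell_id)
        for local_i, f in enumerate(tr.frames):
            amp = rc.amplitude
            if alive is not None and not alive[local_i]:
                amp *= rc.post_kill_intensity_fraction
            by_frame.setdefault(int(f), []).append((ch, tr.pos[local_i], amp))

    for f in range(n_frames):
        frame = np.full((2, nz, ny, nx), float(rc.background_level))
        for ch, pos, amp in by_frame.get(f, []):
            _paint_blob(frame[ch], pos, sigma, amp, rc.voxel_size)
        if rc.poisson_gain is not None:
            frame = rng.poisson(frame * rc.poisson_gain) / rc.poisson_gain
        if rc.read_noise_sigma > 0:
            frame = frame + rng.normal(0.0, rc.read_noise_sigma, size=frame.shape)
        data[f] = np.clip(np.round(frame), 0, 255).astype(np.uint8)

    return VolumeSeries(data=data, voxel_size=rc.voxel_size, dt=dt)
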