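"""End-to-end orchestration: simulate -> (render -> segment -> link) ->
migration analysis -> interaction analysis, with a manifest for
reproducibility and a figure/report stage.

Every stage writes its outputs to the run directory and downstream stages
consume only those files (or the in-memory equivalents); a JSON manifest
records the config, package version and SHA-256 checksums of all artifacts,
so identical config + seed reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import NK, TARGET, RunConfig, config_to_dict
from .interactions import (
    DeathEvent,
    assign_outcomes,
    detect_contacts,
    episodes_to_dataframe,
    interaction_stats,
    nearest_target_distance,
)
from .migration import (
    analyze_track,
    filter_tracks,
    population_summary,
    summarize_track,
)
from .synthetic import render_volumes, simulate_tracks
from .tracks import (
    Track,
    dataframe_to_tracks,
    read_tracks_csv,
    split_by_type,
    tracks_to_dataframe,
    write_tracks_csv,
)
from .volumes import VolumeSeries, link_tracks, segment_volumes, subtract_background

logger = logging.getLogger("nkwell3d")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def run_pipeline(cfg: RunConfig, outdir) -> Dict[str, object]:
    """Execute the configured stages, writing all artifacts under ``outdir``.

    With ``cfg.imaging`` the simulated tracks are rendered into volumes,
    segmented and re-linked, and the analysis runs on the linked tracks;
    otherwise the simulated tracks feed the analysis directly.  Returns a
    dict of in-memory results; a ``manifest.json`` with config and artifact
    checksums is always written last.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: Dict[str, object] = {}
    artifacts: List[Path] = []

    def _run(stage: str, fn):
        logger.info("stage %s", stage)
        try:
            return fn()
        except Exception as exc:  # partial outputs stay on disk
            raise PipelineError(stage, exc) from exc

    # --- simulate -------------------------------------------------------
    def _simulate():
        sim_cfg = dataclasses.replace(cfg.simulation, seed=int(cfg.seed))
        tracks, truth = simulate_tracks(sim_cfg)
        write_tracks_csv(outdir / "tracks_true.csv", tracks,
                         modes=truth.modes, alive=truth.alive)
        truth.contacts.to_csv(outdir / "truth_contacts.csv", index=False)
        truth.kills.to_csv(outdir / "truth_kills.csv", index=False)
        artifacts.extend([outdir / "tracks_true.csv", outdir / "truth_contacts.csv",
                          outdir / "truth_kills.csv"])
        return tracks, truth

    tracks, truth = _run("simulate", _simulate)
    results["tracks_true"] = tracks
    results["truth"] = truth

    # --- imaging path ---------------------------------------------------
    if cfg.imaging:
        def _render():
            ss = np.random.SeedSequence([int(cfg.seed), 1])
            render_seed = int(ss.generate_state(1)[0] % (2**31))
            return render_volumes(tracks, truth, cfg.render, seed=render_seed)

        volumes = _run("render", _render)
        _run("write-volumes", lambda: volumes.to_tiff(outdir / "volumes.ome.tif"))
        artifacts.append(outdir / "volumes.ome.tif")
        results["volumes"] = volumes

        def _segment():
            v = volumes.normalized()
            if cfg.background_subtract:
                v = subtract_background(v)
            det = segment_volumes(v, cfg.segmentation)
            det.to_csv(outdir / "detections.csv", index=False)
            artifacts.append(outdir / "detections.csv")
            return det

        detections = _run("segment", _segment)
        results["detections"] = detections

        def _link():
            linked: List[Track] = []
            offset = 0
            for ch, ctype in ((0, NK), (1, TARGET)):
                det = detections[detections["channel"] == ch]
                if len(det) == 0:
                    continue
                ts = link_tracks(det, cfg.linking, cfg.render.voxel_size,
                                 volumes.dt, cell_type=ctype, id_offset=offset)
                offset += len(ts) + 1
                linked.extend(ts)
            write_tracks_csv(outdir / "tracks_linked.csv", linked)
            artifacts.append(outdir / "tracks_linked.csv")
            return linked

        analysis_tracks = _run("link", _link)
    else:
        # ground-truth deaths truncate target tracks: a dead target loses
        # its label and is no longer followed
        def _truncate():
            out = []
            for tr in tracks:
                alive = truth.alive.get(tr.cell_id)
                if alive is not None and not alive.all():
                    n_alive = int(alive.sum())
                    if n_alive < 2:
                        continue
                    tr = Track(tr.cell_id, tr.cell_type, tr.t[:n_alive],
                               tr.pos[:n_alive], tr.frames[:n_alive])
                out.append(tr)
            return out

        analysis_tracks = _run("truncate-dead", _truncate)
    results["analysis_tracks"] = analysis_tracks

    # --- migration analysis --------------------------------------------
    def _migration():
        nk_tracks, _ = split_by_type(analysis_tracks)
        kept = filter_tracks(nk_tracks, cfg.track_filter)
        profiles = []
        summaries = []
        for tr in kept:
            if len(tr) < cfg.window.window:
                continue
            prof = analyze_track(tr, cfg.window)
            prof.insert(0, "cell_id", tr.cell_id)
            profiles.append(prof)
            summaries.append(summarize_track(tr, prof["mode"]))
        prof_df = (pd.concat(profiles, ignore_index=True)
                   if profiles else pd.DataFrame())
        prof_df.to_csv(outdir / "migration_profiles.csv", index=False)
        pd.DataFrame([s.as_dict() for s in summaries]).to_csv(
            outdir / "track_summaries.csv", index=False)
        artifacts.extend([outdir / "migration_profiles.csv",
                          outdir / "track_summaries.csv"])
        pop = population_summary(summaries) if summaries else {"n_tracks": 0}
        _write_json(outdir / "population_summary.json", pop)
        artifacts.append(outdir / "population_summary.json")
        return prof_df, summaries, pop

    prof_df, summaries, pop = _run("analyze-migration", _migration)
    results["profiles"] = prof_df
    results["summaries"] = summaries
    results["population"] = pop

    # --- interaction analysis ------------------------------------------
    def _interactions():
        nk_tracks, target_tracks = split_by_type(analysis_tracks)
        episodes = detect_contacts(nk_tracks, target_tracks, cfg.contact)
        deaths = [
            DeathEvent(target_id=int(r.target_id),
                       death_min=float(r.death_frame) * cfg.simulation.dt,
                       source="ground-truth")
            for r in truth.kills.itertuples()
        ]
        run_end = cfg.simulation.duration
        episodes, tallies, unattributed = assign_outcomes(
            episodes, deaths, cfg.contact, run_end_min=run_end)
        epi_df = episodes_to_dataframe(episodes)
        epi_df.to_csv(outdir / "episodes.csv", index=False)
        tallies.to_csv(outdir / "nk_tallies.csv", index=False)
        artifacts.extend([outdir / "episodes.csv", outdir / "nk_tallies.csv"])
        stats = (interaction_stats(episodes, n_nk=len(nk_tracks))
                 if episodes else {"n_episodes": 0})
        stats["n_unattributed_deaths"] = len(unattributed)
        if target_tracks and nk_tracks:
            nearest_target_distance(nk_tracks, target_tracks).to_csv(
                outdir / "nearest_target.csv", index=False)
            artifacts.append(outdir / "nearest_target.csv")
        _write_json(outdir / "interaction_stats.json", stats)
        artifacts.append(outdir / "interaction_stats.json")
        return episodes, tallies, stats

    episodes, tallies, istats = _run("analyze-interactions", _interactions)
    results["episodes"] = episodes
    results["interaction_stats"] = istats

    # --- manifest -------------------------------------------------------
    manifest = {
        "package": "nkwell3d",
        "version": __version__,
        "seed": int(cfg.seed),
        "config": config_to_dict(cfg),
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    _write_json(outdir / "manifest.json", manifest)
    results["manifest"] = manifest
    return results


# ---------------------------------------------------------------------------
# reporting


def report(run_dir, out_subdir: str = "report") -> Path:
    """Render summary figures and a statistics table from a finished run.

    Produces: a track plot centred at the origin, speed/confinement
    histograms, a mode pie chart, a transitions histogram, contact/kill
    panels (or a "no contacts" placeholder), and ``summary_table.csv``.
    Deterministic: regenerating from the same run directory gives identical
    tables.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    out = run_dir / out_subdir
    out.mkdir(parents=True, exist_ok=True)

    pop_path = run_dir / "population_summary.json"
    if not pop_path.exists():
        raise FileNotFoundError("run directory lacks population_summary.json; run the pipeline first")
    pop = json.loads(pop_path.read_text())
    istats = json.loads((run_dir / "interaction_stats.json").read_text()) \
        if (run_dir / "interaction_stats.json").exists() else {"n_episodes": 0}

    # track plot centred at origin
    tracks_path = run_dir / "tracks_linked.csv"
    if not tracks_path.exists():
        tracks_path = run_dir / "tracks_true.csv"
    tracks = read_tracks_csv(tracks_path)
    nk_tracks, _ = split_by_type(tracks)
    fig, ax = plt.subplots(figsize=(5, 5))
    for tr in nk_tracks:
        rel = tr.pos - tr.pos[0]
        ax.plot(rel[:, 0], rel[:, 1], lw=0.8)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title("NK tracks, origin-centred")
    ax.set_aspect("equal")
    fig.savefig(out / "tracks.png", dpi=120)
    plt.close(fig)

    if pop.get("n_tracks", 0) > 0:
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        axes[0].hist(pop["speeds"], bins=20, color="tab:blue")
        axes[0].set_xlabel("mean speed (um/min)")
        axes[1].hist(pop["corrected_displacements"], bins=20, color="tab:orange")
        axes[1].set_xlabel("corrected displacement (sqrt(min))")
        axes[2].hist(pop["transitions_per_h"], bins=20, color="tab:green")
        axes[2].set_xlabel("mode transitions per hour")
        for a in axes:
            a.set_ylabel("tracks")
        fig.tight_layout()
        fig.savefig(out / "migration_histograms.png", dpi=120)
        plt.close(fig)

        fr = pop["mode_fractions"]
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.pie([fr["TMAP"], fr["random"], fr["directed"]],
               labels=["TMAP", "random", "directed"], autopct="%.0f%%")
        ax.set_title("time in migration modes")
        fig.savefig(out / "mode_pie.png", dpi=120)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    if istats.get("n_episodes", 0) > 0:
        epi = pd.read_csv(run_dir / "episodes.csv")
        for outcome, g in epi.groupby("outcome"):
            ax.hist(g["duration_min"], bins=15, alpha=0.6, label=outcome)
        ax.set_xlabel("contact duration (min)")
        ax.set_ylabel("episodes")
        ax.legend()
    else:
        ax.text(0.5, 0.5, "no contacts", ha="center", va="center",
                transform=ax.transAxes, fontsize=16)
        ax.set_axis_off()
    fig.savefig(out / "contacts.png", dpi=120)
    plt.close(fig)

    rows = [{"statistic": k, "value": v} for k, v in sorted(pop.items())
            if np.isscalar(v)]
    rows += [{"statistic": f"interaction.{k}", "value": v}
             for k, v in sorted(istats.items()) if np.isscalar(v)]
    pd.DataFrame(rows).to_csv(out / "summary_table.csv", index=False)
    return out
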