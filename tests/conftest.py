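"""Shared fixtures: small synthetic scenes reused across test modules.

Everything is generated at run time from fixed seeds; the expensive
rendered benchmark scene is session-scoped so the segmentation, linking and
acceptance tests share one computation.
"""

import numpy as np
import pytest

import nkwell3d as nk
from nkwell3d.config import (
    ImageRenderConfig,
    LinkingConfig,
    SegmentationConfig,
    SimulationConfig,
)

BENCH_SEED = 2026


@pytest.fixture(scope="session")
def bench_scene():
    """Small imaging benchmark: 5 Brownian cells (speed matched to the
    assay's ~3.2 um/min population mean), 60 frames, 64 x 64 x 10 voxels,
    rendered, background-subtracted, segmented and linked."""
    sim = SimulationConfig(
        n_nk=5, n_target=0, well_size=(66.0, 66.0, 70.0), duration=118.0,
        mode_set=("random",), M_random=4.0, seed=BENCH_SEED,
    )
    tracks, truth = nk.simulate_tracks(sim)
    rc = ImageRenderConfig(frame_shape=(10, 64, 64), voxel_size=(1.1, 1.1, 8.0))
    vols = nk.render_volumes(tracks, truth, rc, seed=BENCH_SEED)
    v = nk.subtract_background(vols.normalized())
    detections = nk.segment_volumes(v, SegmentationConfig(), channels=(0,))
    linked = nk.link_tracks(detections, LinkingConfig(), rc.voxel_size, vols.dt)
    return {
        "sim": sim,
        "tracks": tracks,
        "truth": truth,
        "render": rc,
        "volumes": vols,
        "detections": detections,
        "linked": linked,
    }


@pytest.fixture(scope="session")
def switching_cohort():
    """40 NK cells switching modes with default parameters, 270 frames."""
    sim = SimulationConfig(n_nk=40, n_target=0, seed=11)
    tracks, truth = nk.simulate_tracks(sim)
    return sim, tracks, truth


def straight_track(v=3.0, n=30, dt=2.0, direction=(1.0, 0.0, 0.0), cell_id=0):
    """Noise-free ballistic track at speed ``v`` um/min."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    t = np.arange(n) * dt
    pos = np.outer(t * v, d)
    return nk.Track(cell_id=cell_id, cell_type="NK", t=t, pos=pos)
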