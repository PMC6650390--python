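# Methods

This note documents the models, parameter choices and numerical decisions
behind `nkwell3d`, and what the synthetic assay does and does not show
about real data.

## Synthetic assay model

**Trajectories.**  NK cells follow a three-state continuous-time Markov
chain over migration modes.  Dwell times are exponential with mean
`dwell_mean` (default 106 min, the observed population mean residence time
in a mode); on leaving a state the cell jumps to one of the other two
modes with equal probability, so long-run occupancy is 1/3 per mode.
Within a mode, steps over one frame interval Δt are:

- **TMAP** (arrest) and **random**: isotropic Gaussian with per-axis
  variance 2·M·Δt, so the 3D MSD slope is 6M.  Defaults M_tmap = 1
  µm²/min (below the 4.9 µm²/min threshold) and M_random = 15 µm²/min
  (clearly above it).
- **directed**: displacement v·Δt (default v = 6 µm/min) along a unit
  heading drawn once per mode episode, producing α → 2 windows.

Target cells are Brownian with M = 0.3 µm²/min (near-immotile, matching
their high confinement in the assay).  The well (default
450 × 450 × 300 µm) has reflecting walls; a reflected directed cell also
flips the corresponding heading component.  Cells carry an excluded
volume: any step that would bring two centres within `min_separation`
(default 8 µm, one NK diameter) is rejected and the cell stalls for that
frame.  This matters for rendering — interpenetrating blobs are an
artifact no segmentation could undo — and is a soft constraint (separation
can transiently dip below the bound when several cells move at once).

**Kills.**  At the onset of each fresh NK–target contact (centre distance
below 20 µm), the target is committed to die with probability
`p_kill_per_contact` (default 0.57, the observed cytolytic fraction of
contacts).  Death occurs an exponential delay after onset
(`kill_delay_mean`, default 20 min; the assay gives no kinetic model, so
the value is a configuration choice inside the 30 min attribution window).
Dead targets freeze, are flagged in the ground truth, and are rendered at
`post_kill_intensity_fraction` (default 0.1) of their amplitude,
emulating calcein leakage.

**Rendering.**  Each live cell becomes an anisotropic Gaussian blob with
σ = (2.5, 2.5, 4) µm — cell size convolved with the confocal PSF; in z an
8 µm cell contributes σ ≈ 2.7 µm and the axial PSF of a 10×/0.45 NA
system ≈ 3 µm — at amplitude 200 of the 8-bit range (calcein-bright
cells) over a background of 8.  Poisson noise (gain 1) and Gaussian read
noise (σ = 2) are applied last; output is uint8, axes T,C,Z,Y,X, NK in
channel 0 and targets in channel 1, written as OME-TIFF with voxel-size
metadata.

**What the generator does not emulate.**  Collagen-fibre texture and the
reflection channel, photobleaching, cell-shape changes, chemotaxis,
z-dependent attenuation, and any conjugation behaviour: simulated NK
cells do not pause at targets, so synthetic conjugations are much shorter
(~5–10 min) than the 47.9 min observed in the assay.  Passing tests
therefore demonstrate that the algorithms recover what the model
contains — mode structure, positions, identities, kill attribution — not
that the model reproduces every population statistic of the real assay.

## Segmentation and linking

Stacks are converted to [0, 1] floats; the static background is the
per-voxel temporal minimum.  Segmentation: difference-of-Gaussians with
σ = 1 and 3 xy-pixels (both divided by 8 in z), threshold 0.02 applied to
the band-passed image (the text order of the original pipeline implies
the filtered image, and thresholding raw intensities would defeat the
band-pass), watershed on the negated band-passed image after h-minima
suppression at h = 0.15 with seeds at the suppressed regional minima
restricted to the thresholded mask (components without a seed survive
whole), hole filling (2D per slice, then 3D with 6-connectivity), and
removal of regions under 5 voxels.  Centroids are intensity-weighted and
reported in µm.

Linking is per-frame optimal bipartite assignment replacing the original
global multi-hypothesis linker: a link scores the anisotropic Gaussian
log-density of the displacement (σ = 6 xy-voxels, 0.5 z-voxels) plus the
one-cell count prior log 0.7; unmatched tracks/detections score
log p_disappear / log p_appear (both 0.001).  Links beyond 5σ on any axis
are forbidden.  Death and division are disabled and there is no gap
closing: a missed detection ends the track.  Detections larger than 1.6×
the median object volume are treated as 2+-cell clusters (the count
class with prior 0.1) and cannot be linked through, so touching cells
break tracks instead of swapping identities; the factor sits midway
between the volume of one cell and of two merged cells and is exposed in
`LinkingConfig`.

Track-set comparison pairs tracks by greatest temporal overlap with ties
broken by smallest mean centre distance (overlap alone cannot separate
tracks that span identical frame ranges), then scores co-timed points by
3D distance against a 2 µm tolerance.

## Migration analysis

Tracks shorter than 60 min, or with any consecutive z-jump strictly over
40 µm, are excluded.  The 25-point window is centred (points −12…+12);
the 12 points at each track end carry no label and are excluded from all
denominators.  The MSD fit uses lags 1–6 (lag 0 would make the log fit
undefined) with an unconstrained intercept: localization noise produces
offsets, and on noise-free data the intercept vanishes so the slope-only
behaviour is recovered exactly.  Negative fitted slopes clip M to 0
(arrest); windows containing a zero MSD lag leave α undefined and the
point is classified by M alone.  Both profiles are smoothed by a centred
5-point rolling average (the original description names rolling averages
without a length; 5 points ≈ 10 min balances jitter suppression against
switch latency and is exposed in `WindowConfig`).  Arrest takes
precedence where both criteria fire, since the M threshold is applied
first; the directed rule requires α > 1.5 on ≥ 10 consecutive labelled
points.  TMAP-fraction groups are low < 10%, medium 10–90%, high > 90%.
Transitions per hour use each track's labelled span, not the nominal
assay duration.  Dwell times from labels count only completed visits
(runs bounded by switches on both sides), which biases them below the
generator's 106 min for 9 h tracks; the generator-level estimate in the
acceptance script instead averages the drawn dwells.

The 4.9 µm²/min threshold is derived, not hard-coded:
D = k_B T/(6π η r) for d = 8 µm at T = 310.15 K with η = 6.9 × 10⁻⁴ Pa·s
(water at 37 °C, which reproduces the printed value; both constants are
arguments of `brownian_threshold`).

Median windowed M carries a ~10–12% downward bias on Brownian tracks
(short correlated fits over overlapping window pairs); this is inherent
to the 6-point estimator and well inside the 20% recovery band the tests
enforce.

## Interaction analysis

Contacts use strict `< 20 µm`; equality is non-contact.  Episodes
separated by more than `gap_tolerance` frames (default 0 — no merging)
are distinct; single-frame episodes last one frame interval.  Death is
called from an intensity trace at the first frame that stays below half
the running pre-drop baseline for ≥ 3 frames.  A death is attributed to
the qualifying episode that overlaps it (latest start on ties), else to
the nearest preceding end within the 30 min window; episodes still open
at the end of the recording with no death are "unresolved" and excluded
from the cytolytic fraction's denominator.  Duration summaries use the
sample (n−1) standard deviation.  Simultaneous multi-NK contacts are
scored as separate episodes.

## Pipeline and reproducibility

One global seed governs every stochastic stage; per-stage generators are
spawned from `SeedSequence(seed, stage)` so disabling the imaging stage
leaves the simulated tracks unchanged.  All physical quantities are
serialized in µm and min; voxel units never leave the volume-processing
layer.  The run directory holds every intermediate as CSV/JSON plus a
manifest with SHA-256 checksums; identical config + seed reproduces
identical checksums.

Problem sizes in the test suite and acceptance script — e.g. the 5-cell
64 × 64 × 10-voxel benchmark scene (Brownian M = 4 µm²/min, chosen so the
mean speed ≈ 3.2 µm/min matches the assay's population mean), 200-track
recovery cohorts, 8 simulated wells for population statistics — are the
package's default desk-scale configurations; all scale up through the
same configs.

## Known limitations

- Frame-to-frame linking cannot re-identify a cell after a missed
  detection or a merge; fragment counts exceed cell counts by design.
- Oversegmented or multi-cell objects are excluded from linking rather
  than merged into neighbours.
- The death-call rule assumes a stable pre-death baseline; slow
  photobleaching would need a trend-corrected baseline.
- Mode labels near switches are intrinsically blurred by the centred
  window (~12 frames on each side of a switch).
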