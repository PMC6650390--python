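# nkwell3d

3D single-cell migration and cytotoxicity analysis for collagen-filled
microwell assays, in which natural killer (NK) cells and tumour target
cells are embedded in a collagen-I matrix inside 450 × 450 × 300 µm wells
and imaged as two-channel confocal z-stacks (≈1.1 × 1.1 × 8 µm voxels)
every 2 minutes for up to 9 hours.  The package is for researchers who
want to quantify, from such time-lapse volumes or from pre-computed track
tables, (i) how individual NK cells move through a 3D matrix —
alternating between migration arrest, random walking and directed runs —
and (ii) how often their contacts with target cells end in a kill.

## What it computes

**Tracking.**  Volumes are background-subtracted (per-voxel temporal
minimum), band-pass filtered with a difference-of-Gaussians (σ = 1 and 3
xy-pixels, both divided by 8 in z), thresholded at 0.02, split into cells
by a watershed after h-minima suppression (h = 0.15), and cleaned of
regions under 5 voxels.  Detections are linked frame-to-frame by optimal
bipartite assignment under an anisotropic Gaussian motion model
(σ = 6 xy-voxels, 0.5 z-voxels) with explicit appearance/disappearance
probabilities; there is no gap closing.

**Migration modes.**  For a track r(t) sampled at Δt, a 25-point window
centred on each time point gives the local mean-squared displacement

    MSD(t_n) = 1/(N−n) Σ_i ‖r_{i+n} − r_i‖²,   t_n = n·Δt .

A linear fit to the first 6 lags yields the motility coefficient *M*
through MSD = 6 M t, and the log–log slope over the same lags yields the
anomalous exponent α (≈1 diffusive, 2 ballistic).  After smoothing, time
points with M < 4.9 µm²/min — the Stokes–Einstein diffusivity
D = k_B T / (6π η r) of an 8 µm sphere in water at 37 °C — are transient
migration arrest periods (TMAPs); runs of α > 1.5 lasting ≥ 10 points are
directed migration; the rest is random movement.  Per-track summaries add
mean speed, the confinement index ‖r_end − r_1‖/d_tot · √t_tot, mode
fractions and switching rates.

**Interactions.**  NK–target contacts are maximal runs of frames with
centre-to-centre distance < 20 µm; target death is read from sustained
loss of calcein fluorescence (or simulation ground truth); an episode is
cytolytic when its target dies during the episode or within a 30 min
attribution window after it.  Summaries include conjugation durations
(mean ± SD), per-NK contact/kill tallies and a Mann–Whitney U comparison
of cytolytic vs non-cytolytic durations.

**Synthetic assay.**  Because every stage needs ground truth to be
testable, `nkwell3d.synthetic` simulates the assay end-to-end: NK cells
switch between confined, Brownian and persistent motion as a three-state
Markov process (exponential dwells, mean 106 min), targets are slow
Brownian particles, contacts can trigger kills, and the whole scene can be
rendered into noisy anisotropic 8-bit voxel stacks with per-frame truth
(positions, modes, contacts, kills).

## Worked example

`examples/migration_modes.py` simulates 25 mode-switching NK cells and
runs the rolling-window classification against the generator's truth:

```
arrest threshold: M < 4.94 um^2/min (8 um particle, water at 37 C)
frame-level agreement with ground truth: 90.6 % (6175 labelled points)
  classified time in     TMAP: 19.5 %
  classified time in   random: 42.3 %
  classified time in directed: 38.2 %
mode transitions per hour (cohort mean): 0.65
mean completed dwell: 55 min
```

The threshold line is the derived Stokes–Einstein value behind the
4.9 µm²/min arrest cut-off.  Agreement is ~91% because the centred
window blurs labels near mode switches; the classified mode fractions
track the generator's occupancy.  The other scripts in `examples/` cover
simulation (`simulate_cohort.py`), the voxel pipeline
(`imaging_pipeline.py`), contact/kill scoring (`contacts_and_kills.py`)
and the orchestrated pipeline with figures (`full_pipeline.py`).

A thin CLI wraps the same functions:

```
nkwell3d run --config cfg.yaml --out rundir
nkwell3d report rundir
nkwell3d segment --volumes v.ome.tif --out detections.csv
```

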