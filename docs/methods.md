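# Methods

This note records the models behind `plaquebeads`, the defaults and why
they were chosen, and what the synthetic validation does and does not
demonstrate.

## Imaging model

A specimen is a set of per-channel voxel grids over a physical box of
`width_um × height_um × depth_um`. Voxel `(k, j, i)` covers the half-open
box `[i·s, (i+1)·s) × [j·s, (j+1)·s) × [k·Δz, (k+1)·Δz)` and is sampled at
the voxel centre; grid dimensions are `ceil(extent / step)`. All truth
coordinates are continuous, scene-global, in micrometres, 0-based at the
voxel-corner origin.

Defaults:

| parameter | default | rationale |
|---|---|---|
| lateral pixel | 0.25 µm/px | a 1 µm bead spans ~4 px, so the 0.5–1.5 µm size gate maps to ≥ 2 px structures |
| axial step Δz | 10 µm | the tiled-acquisition protocol the simulator emulates |
| tile overlap | 10 % | same |
| channels | SHG 380–440, green 490–530, red 530–650 nm | collagen second harmonic; beads + elastin/collagen autofluorescence; neutral lipid |

### Background textures

Phenomenological, not optical-physics: the SHG channel carries
positive-rectified anisotropic smoothed noise (fibre streaks, σ ≈ 0.5 µm
across × 4 µm along), the green channel a constant autofluorescence floor
(30 a.u.) with slow spatial variation (σ 8 µm, amplitude 8), the red
channel Gaussian lipid blobs (12 blobs, σ 4 µm, amplitude 50). Zero
amplitudes give exactly empty tissue.

### Beads

A bead is a uniform disk of diameter 1 µm (default) blurred laterally by a
Gaussian of σ 0.3 µm and spread axially by a Gaussian of σ 6 µm; the
lateral profile is the radially smoothed step
`L(r) = ½ erfc((r − R)/(√2 σ_lat))` and the axial factor
`exp(−(z − z₀)²/2σ_ax²)`, with peak 100 a.u. above background. The large
axial σ models the strong axial elongation of a low-NA objective in
scattering tissue; it is the property that makes one bead visible in at
least two 10 µm-spaced sections. Beads are planted with centres at least
half a z-step inside the sampled plane span, so the two nearest sections
are never more than one step away; with σ_ax = 6 µm the signal one step
from focus retains 25 % of its peak, comfortably above the detection
threshold. An earlier candidate default (σ_ax = 2.5 µm) retains only
0.03 % one step from focus and cannot reproduce two-section visibility;
it was rejected for that reason.

Isolated beads keep a minimum *lateral* centre separation of 3 µm (twice
the maximum detectable diameter) — lateral, not 3D, because counting
happens on z-projections where axial distance cannot separate two beads.
A configurable clump fraction (default 5 %, matching the observed rarity
of clumped beads) groups beads into clusters of 2–3 with members within
one diameter of each other.

### Noise

Photon-limited detector model: recorded = Poisson(gain·signal)/gain +
N(0, σ_read), with gain 5 photons per intensity unit and σ_read = 2 a.u.
No detector gain figures exist for the original instrument, so these are
uncalibrated but give a realistic shot-noise-limited image (background
SNR ≈ 10 per plane). Bead profiles are added after the noise pass;
per-bead shot noise is negligible at these amplitudes and omitting it
keeps the planted signal exactly known.

## Detection

Per tile, the bead-channel stack is sum-projected (float64, no
saturation). The local background is a median filter of radius 5 µm — for
radii above 6 px it is computed on a block-averaged copy of the image and
re-expanded, which is orders of magnitude faster and indistinguishable for
backgrounds varying slowly relative to a bead footprint. Pixels exceeding
background + threshold form 8-connected components.

Each component is then **sized at half of its own peak** (never below the
threshold): the equivalent-circle diameter `2√(area/π)·s` of that half-max
core is what the 0.5–1.5 µm gate tests. Sizing at the detection threshold
itself would make the measured diameter grow with bead brightness (a
2× brighter bead would look ~40 % wider), whereas the half-max core is
brightness-invariant — the analogue of sizing a bead image by its visible
core rather than its faint skirt. Undersized cores are discarded as
noise; oversized cores are watershed-split at internal intensity maxima
(minimum peak separation = the minimum bead diameter) when at least two
maxima exist, else emitted once with a clump flag. Centroids are
intensity-weighted and sub-pixel; the size-gate invariant applies to
unflagged detections (a flagged unsplittable clump deliberately reports
its true, oversized diameter).

**Threshold calibration** scans a grid and returns the value minimising
the summed absolute count error against reference counts on
representative composites, ties broken toward the smaller threshold
(counts, not positions, are compared — that is what the reference,
visual inspection, provides). On the simulator's default brightness
scale the calibration lands at 14–16 a.u.; `DetectionParams` defaults to
15 and any new data set should be re-calibrated.

**Best focus**: for a detection, the per-plane signal is the mean
background-subtracted intensity over a disk footprint of the detection's
radius (background = median of a surrounding ring); the best-focus plane
is the argmax over z, with ties to the lowest index, and `None` if no
plane reaches the (higher) focus threshold — the stricter cutoff used for
axial-distortion correction.

## Mosaic

Tile offsets come from the stage model: row-major, step
`round((1 − overlap)·extent)` per axis; no cross-correlation registration
(the simulated stage is exact, and residual sub-pixel rounding error is
absorbed by the de-duplication radius). Stitching resolves overlaps by
per-pixel maximum — averaging would dim a bead against the neighbouring
tile's background — with first-tile-wins on exact ties and a provenance
map recording the winning tile.

De-duplication visits detections brightest-first (deterministic position
tie-break) and drops any detection with an already-kept detection from a
*different* tile within 1.5 µm (the maximum bead diameter: one physical
bead cannot yield two centres farther apart than its own diameter).
Same-tile neighbours are never merged — they are genuinely distinct
objects. The procedure is idempotent and independent of tile processing
order, and operates on the 2D global coordinates of the sum projections,
matching where the counting happens.

## Statistics

Per-group mean and SEM (s/√n, n−1 denominator; a single-animal group
reports SEM 0 with a flag rather than NaN). Fold change is the ratio of
group means; percent reduction is 100·(1 − m_t/m_c) with a first-order
delta-method standard error
`100·√((sem_t/m_c)² + (m_t·sem_c/m_c²)²)` — the convention adopted for
the reduction's "±" since the original computation is unstated. The
*t*-test is Student's (pooled variance), not Welch, because that is the
named test; it is one-tailed with the direction supplied explicitly in
configuration, because the hypotheses (later > earlier; treated <
control) are fixed a priori and a direction chosen from the data would
invalidate the p-value.

## Flow gating

Rectangular live gate in (FSC, SSC) and scalar thresholds on CD115, Gr1
and FITC — actual cytometer gate geometry is unavailable, and rectangles
suffice for the well-separated simulated populations (monocyte CD115
mean 10 pooled σ above non-monocytes). Bead-positive Gr1-low cells are
reported as a percentage of **all** monocytes by default (the convention
in which 5.8 % is quoted), with the Gr1-low denominator available. The
CD45 channel is not part of the gate chain. Simulated compositions:
90 % live, 12.7 % monocytes of leukocytes, 50 % Gr1-low of monocytes,
5.8 % bead-positive of monocytes, confined to the Gr1-low class.

## Presentation operations

Axial-distortion correction zeroes the bead channel of the stitched
volume and re-renders each focused detection as a uniform disk (default
1 µm, the physical bead diameter) in its single best-focus plane at the
detection's peak intensity; overlapping markers composite by maximum
(union), an explicit choice since no compositing rule is stated for the
original reconstructions. Display dilation stamps a binary union of
20 µm disks. Channel smoothing is a normalized 7×7 Gaussian with
σ = 7/6 px, so the stated support spans ±3σ (the σ itself is unstated
anywhere and had to be chosen). None of these operations participates in
counting; counts before and after are identical by construction and by
test.

## Validation scale and what it shows

The recovery experiments run at desk scale: per-animal specimens of
60×60×40 µm (2×2 mosaic, 4 sections) rather than whole aortic arches,
with per-animal bead counts Poisson-distributed around means of 20 vs 60
(fold experiment, 5 animals/group) and 60 vs 37.8 (reduction experiment,
3 animals/group), pooled over 20 seeded replicates; gating runs ten
10,000-event tables and averages the recovered percentages to suppress
Monte-Carlo noise. These sizes exercise every pipeline stage — including
beads landing in overlap strips — while keeping a full acceptance run
around one minute.

Passing these tests shows the pipeline is unbiased to within a few
percent under its own generative model, with known ground truth and
well-separated populations. It does **not** show robustness to what the
generator omits: motion artifacts and raster-synchronized streaks of
flowing cells, vessel curvature and depth-dependent attenuation,
illumination inhomogeneity across tiles, stage-offset errors requiring
registration, autofluorescent debris in the bead band, or antibody
spillover in cytometry. Clumped beads are the one modelled difficulty
that is *not* fully recovered: 2–3 beads within one diameter are
frequently counted as one (flagged), producing a ~2 % undercount in
dense samples and a correspondingly small compression of recovered
effect sizes — visible as recovered fold changes of ≈ 2.8–2.95 against
a planted 3.0.

## Numerical choices and degenerate inputs

- Sum projection accumulates in float64 regardless of input dtype.
- Pixel index ↔ micron convention: index `i` is the centre of
  `[i·s, (i+1)·s)`, so `x_um = (i + offset + 0.5)·s`.
- Zero-weight components fall back to unweighted centroids.
- `argmax` ties (best focus, stitching) resolve to the lowest index /
  earliest tile, making every stage deterministic.
- Empty inputs raise immediately with a named offender (e.g. a missing
  tile names its row, col and channel).
- All randomness flows through `numpy.random.default_rng` seeded at the
  API boundary; identical (config, seed) pairs are bitwise-reproducible.
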