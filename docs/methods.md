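# Methods

This note documents the measurement models implemented in `spheromatrix`,
the synthetic scenes used to validate them, the tunable parameters that
matter, and the numerical choices made where the design was genuinely
open.

## Coordinate and calibration conventions

Arrays are ordered `(T?, Z?, C, Y, X)` with absent axes dropped.
Coordinates are 0-based with pixel centers at integer indices; the
physical position of index *i* is *i* × pixel_size (µm). Every metric is
computed in µm via `AcquisitionMetadata` (pixel_size, z_step,
frame_interval), never in pixels, so results are invariant to the camera
calibration. Calibration has no defaults: a stack without it is an
error, because every downstream quantity depends on it.

"Around the spheroid" means distance from the spheroid **edge** measured
by a Euclidean distance transform of the mask exterior (anisotropy-aware
in 3D, with z sampled at the z-step). The 3D text of the underlying
assay states distances "away from the spheroid edge" explicitly; the 2D
convention follows it (a centroid-anchored variant is available via
`AnalysisConfig.ring_anchor`). EDT distances are measured to the nearest
mask pixel center and can therefore exceed the continuum distance to the
ideal boundary by up to one pixel; ring membership is half-open
[lo, hi) so each pixel belongs to exactly one ring.

## Spheroid segmentation

**2D frames.** Otsu threshold → largest connected component (ties broken
by proximity to the image center) → convex hull as the initial level
set → morphological Chan–Vese evolution. A region-based contour was
chosen over an edge-based one because spheroid edges are diffuse; the
iteration cap (200) and the early-stop tolerance (fraction of changed
pixels per 10-iteration block < 1e-3) are config. A final contrast gate
(mask mean > 2× background median) rejects structureless noise frames.
On a rendered 120 µm disk at 10:1 contrast the segmented area is within
3% and the centroid within 0.5 µm.

**3D stacks.** Per slice: Canny edges with hysteresis thresholds at the
50th/90th gradient quantiles (config), σ = 2 px pre-smoothing →
morphological closing (disk 3) → fill → small-object and contrast
filtering. Slices without a sufficiently large, sufficiently bright
closed contour are marked absent. The reconstructed solid gives volume
(Σ slice areas × z-step, within 7% for a 50 µm sphere at 5 µm z-step),
the volume-weighted centroid (within one voxel), and an equivalent
radius (3V/4π)^(1/3).

**Radius from the density spike.** Beads crowd at the spheroid surface,
producing a spike in the radial bead-density profile. The spike shell's
center distance is taken as the radius, provided its density exceeds
2× the median of occupied shells (when fewer than three shells are
occupied — beads confined to the surface — the all-shell median is the
baseline instead). A flat profile raises `no_spike_found` and the
pipeline falls back to the segmentation radius, flagged.

## Bead localization, linking and speed

Localization is the classic centroid scheme: band-pass (σ = 1 px
Gaussian minus a feature-diameter boxcar), local maxima above both a
percentile threshold (64th of positive band-passed values) and a robust
noise floor (5× σ estimated from the median of the half-normal positive
tail), then iterative intensity-weighted centroid refinement in the
feature window. A relative mass floor (1% of the brightest candidate)
removes band-pass ringing artifacts. All thresholds scale with the
image, so detection is invariant to uniform intensity rescaling. On
synthetic spots: < 0.01 px error noise-free, recall ≥ 0.95 and RMSE
≤ 0.2 px at SNR 10 with spacing ≥ 2 feature diameters. 3D localization
runs the 2D detector per slice and merges across a 3-slice window with a
mass-weighted z centroid — full 3D fitting is unnecessary at a 5 µm
z-step and much more expensive.

Linking solves, per frame pair, the assignment minimizing summed squared
displacement, with unmatched detections charged max_displacement²
(birth/death); no gap closing. This equals the exhaustive-enumeration
optimum on every tested instance (≤ 6 particles/frame). A step
contributes to the speed metric if its **start** position lies in the
0–100 µm annulus; speed = |Δx|/Δt, averaged per interval with the
contributing count reported. Intervals with no contributor report an
absent value with a flag, never zero. Per-trajectory net-displacement
averaging is available via `speed_mode="net"`.

## Density metrics

*2D fold change*: annulus mean intensity per frame, re-segmented each
frame, divided by the hour-0 value (identically 1 at hour 0).
*Persistence*: 30 µm rings from 0 to 240 µm, normalized by the
210–240 µm reference ring; rings clipped by the field of view carry a
coverage fraction and are flagged below 25% coverage. The 30 µm width
is wide enough to average over noise and narrow enough to resolve the
decay. *3D shell density*: Σ(integrated bead intensity)/analytic shell
volume 4/3·π(r³out − r³in), shells of 10 µm anchored at the estimated
radius; a per-bead-mean variant sits behind
`shell_density_mode="per_bead_mean"`. Shells clipped by the image
boundary get a Monte-Carlo volume correction (1e5 samples, seed derived
from `rng_seed`). The 3D fold change compares the shell containing
r + 25 µm at hour 6 and hour 0, each stack using its own estimated
radius so the query is well-defined when the radius differs; the single
containing shell (not an average of neighbors) is used. All fold
changes are invariant to global multiplicative intensity scaling.

## Hole quantification

Candidate dark regions in each bead-channel slice are seeded at the 20th
intensity percentile of the extraspheroidal area. Each candidate's
boundary is then refined at the local half-height between its floor and
the slice-wide matrix level (the slice median is used as the matrix
reference rather than a local halo, which is unreliable when dominated
by bright bead light; the half-height/FWHM convention places the contour
at the true edge of a smoothed step, where a fixed percentile would
inflate the area by ~2 px of radius). A candidate is kept only if

1. the refined region itself is dark (median < 0.5× matrix level) —
   this rejects thresholds that percolate through gel texture;
2. its boundary coincides with Canny edges computed at a coarse scale
   (σ = 6 px, so individual bead spots do not dominate the gradients);
3. it lies within 25 µm of the spheroid boundary (holes form near
   spheroids; distal dark patches are flagged `distal_void_ignored`);
   on slices where the spheroid is absent, adjacency is tested against
   the nearest segmented slice;
4. it exceeds 100 µm² (below any biologically plausible hole, above
   single-bead voids); and
5. it is genuinely bead-free: localized beads above 1 per 10³ µm²
   veto it.

Near a void's axial caps the slice is thin and out-of-focus light raises
its floor, so a stack-level pass grows the hole into slices adjacent to
confidently segmented ones, thresholding at the half-height between the
established void floor and the slice matrix level, restricted to
components overlapping the neighbor mask and capped at 2× its area
(axial growth should taper, not balloon). Volume = Σ area × z-step;
the 2D hole size is the maximum-area slice (ties to the lowest index).
Multiple disjoint holes are summed per slice. On a synthetic
40×40×30 µm ellipsoid the volume is within ~3% of the analytic slice
sum at z-steps 10, 5 and 2.5 µm, with monotonically decreasing error.
Manually traced outlines can be imported from ROI CSVs (shoelace areas)
for comparison.

## Group statistics

Fold changes are tested against 1 with a two-tailed one-sample Wilcoxon
signed-rank test: exact by full 2ⁿ sign enumeration for n ≤ 12, normal
approximation with tie and continuity corrections above. Zero
differences are dropped (Wilcoxon's original rule; Pratt's method via
`zero_policy="pratt"`). The family of p-values is adjusted by
Benjamini–Hochberg step-up (delegated to statsmodels behind the module
surface) at FDR 5%, and significance labels (`**` p < 0.01, `*`
p < 0.05) come from the adjusted p when correction applies. Across
treatment groups: Kruskal–Wallis (tie-corrected H, chi-square p; scipy
behind the surface, with H = 0 for all-identical data) followed by
Dunn's pairwise z = (R̄ᵢ − R̄ⱼ)/SE with pooled-rank tie correction,
reported unadjusted by default (BH across pairs optional) — the
correction family in the source procedure is the Wilcoxon family, not
the post-hoc pairs. Error bars are s.e.m. (n−1 sd over √n). Under an
all-null simulation (8 log-normal fold-change groups, 2000 replicates)
the empirical FDR of the full procedure is ≈ 0.04–0.06.

## Synthetic scenes: what they emulate, and what they do not

The generator renders a bright circular/spherical spheroid (Gaussian-
smoothed disk per slice), point beads as isotropic Gaussians
(σ = 1.5 px lateral, 2.5 µm axial), a diffuse `matrix_background`
wherever gel exists — emulating the out-of-focus fluorescence of a
bead-laden gel in a confocal section, absent inside the spheroid and
inside holes, which is what makes voids dark as they are in real data —
plus additive Gaussian noise, clipped at zero.

Timelapses advect beads radially inward with
v(d, t) = v0·e^(−d/L)·e^(−t/τ) applied to the continuous positions in
five sub-steps per frame (rendering discretizes afterwards, so ground
truth is exact). Beads stop 0.5 µm outside the surface
(`edge_clearance`) and accumulate — densification is emergent, not
painted. Defaults are the study conditions throughout: 512×512 µm field
at 1 µm/px, 120 µm spheroid, 13 half-hour frames (hours 0–6), 2000
beads, v0 = 3 µm/h, L = 100 µm, τ = 6 h; z-stacks use 5 µm steps,
≤ 10⁴ beads, and 5% of beads at the spheroid surface (the density
spike used for radius estimation). Z-stacks can also impose a radial
density factor f(d) = 1 + A·e^(−d/Ld) directly, for targeted tests of
the 3D metrics; because the generator places a fixed bead count, the
realized density is f(d)/⟨f⟩, and the ground-truth query accounts for
that normalization.

Passing these tests shows the measurement chain recovers known motion,
density and geometry from realistically rendered images. It does not
exercise fiber-network mechanics, anisotropic or depth-dependent PSFs,
photobleaching, stage drift, non-spherical spheroids, or multi-spheroid
fields — real data with those features may need parameter adjustment,
and the qc flags are the first place to look.

## Numerical and policy choices

- Linking ties break by detection index order; max-area-slice ties by
  lowest slice index; largest-component ties by centroid proximity to
  the image center. All randomness (Monte-Carlo volumes, simulation)
  derives from explicit seeds; the full pipeline is bit-reproducible.
- Problem sizes in the test-suite scenes (300×300×40 z-stacks, 8–10k
  beads, 2000-replicate statistical nulls) were chosen as the smallest
  scenes in which each metric's tolerance is meaningful at desk scale.
- The "no radial trend" check on uniform fields uses a Poisson-weighted
  least-squares slope (shell count variances differ several-fold across
  shells; an unweighted fit misreads correlated Poisson noise as trend).
- Stages that fail inside `run_pipeline` record qc flags
  (`segmentation_failed`, `no_beads_detected`, `no_spike_found_t0`,
  `distal_void_ignored`, …) instead of raising; nothing is excluded
  silently.

## Known limitations

- Detection merges beads closer than about one feature diameter;
  intensity-sum shell densities are robust to merging but counts are
  not, so `n_beads` under-counts in crowded regions.
- The hole detector assumes voids darker than half the local matrix
  level; shallow or bead-contaminated voids are (deliberately) rejected.
- The 2D active contour assumes one spheroid per field of view.
- Persistence profiles need the field to extend 240 µm beyond the
  spheroid edge; smaller fields yield a qc flag rather than a profile.
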