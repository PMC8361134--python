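# spheromatrix

Quantification of local cell–matrix interactions around multicellular
spheroids embedded in bead-labeled collagen gels.

Fibroblast spheroids cultured in 3D collagen pull on, densify, and
eventually tear the surrounding matrix. When fluorescent polystyrene
microspheres are mixed into the gel, their motion and crowding report the
matrix's deformation. This package turns two-channel fluorescence stacks
(a cell/spheroid channel and a bead channel) into the standard metrics of
that remodeling, for people running spheroid-in-gel contraction or
invasion assays:

- **Collagen pulling speed** — beads are localized to sub-pixel precision
  (band-pass + intensity-weighted centroid, Crocker–Grier style), linked
  into trajectories by globally optimal assignment, and the mean per-step
  speed v̄ (µm/h) is averaged over the annulus 0–100 µm from the spheroid
  edge.
- **2D collagen density fold change** — mean bead-channel intensity Ī(t)
  in the same annulus, re-segmented every frame (Chan–Vese active
  contour), reported as Ī(t)/Ī(0).
- **Persistence distance** — Ī binned into 30 µm rings out to 240 µm and
  normalized by the outermost (210–240 µm) ring, giving a dimensionless
  decay profile of the densification signal.
- **3D collagen density fold change** — beads localized in z-stacks,
  assigned to spherical shells around the spheroid centroid (Canny
  per-slice segmentation; radius from the bead-density spike at the
  spheroid surface), density = Σ(bead intensity) / shell volume; the fold
  change is read in the shell 25 µm from the spheroid edge,
  hour 6 / hour 0.
- **Hole area and volume** — bead-free voids adjacent to the spheroid are
  segmented per z-slice (percentile seed, half-height boundary
  refinement, Canny support, bead-freeness veto), summed as
  V = Σ areaᵢ · Δz, with the 2D hole size taken at the maximum-area
  slice.
- **Group statistics** — two-tailed one-sample Wilcoxon signed-rank tests
  of fold changes against 1 with Benjamini–Hochberg control at FDR 5%,
  Kruskal–Wallis with Dunn's post-hoc across treatment groups,
  reference-group (e.g. TGF-β-only) normalization, s.e.m. error bars and
  `*`/`**` significance labels.

A synthetic-scene generator (`spheromatrix.synthetic_data`) renders
spheroid-in-gel timelapses and z-stacks with exact ground truth
(advection fields, density profiles, analytic hole geometry), so every
metric is testable without any microscope data.

## Worked example

```python
import numpy as np
import spheromatrix as sm

config = sm.AnalysisConfig()

# a spheroid pulling beads inward at 3 µm/h, no decay, 13 frames of 0.5 h
params = sm.SimulationParams(n_beads=500, pull_speed_v0=3.0,
                             pull_decay_length=np.inf,
                             pull_decay_time=np.inf, rng_seed=1)
stack, truth = sm.simulate_timelapse(params)

geom = sm.segment_spheroid_2d(stack.channel("cell")[0], config)
bead = stack.channel("bead")
frames = [sm.detect_beads(bead[t], config, exclude_mask=geom.mask, frame=t)
          for t in range(stack.n_frames)]
trajs = sm.link_detections(frames, config.max_displacement)
speed = sm.annulus_speed(trajs, geom, config, frame_interval=0.5)
print(f"spheroid radius: {geom.equivalent_radius_um:.1f} um")
print("mean speed (um/h):", round(np.mean(speed.speeds), 3))
```

prints

```
spheroid radius: 60.0 um
mean speed (um/h): 2.854
```

The recovered radius matches the simulated 60 µm spheroid, and the mean
annulus speed sits within a few percent of the imposed 3 µm/h pull (it is
slightly below because beads that reach the spheroid boundary stop there
and accumulate — the same crowding that the density metrics then pick
up).

The same stages are scriptable from a shell:

```bash
spheromatrix simulate --preset timelapse --seed 1 --out scene/
spheromatrix track --stack scene/timelapse.tif --out traj.csv
spheromatrix run --samples sheet.csv --out results/   # full pipeline
spheromatrix stats --values folds.csv --metric density2d --out stats.csv
```

`spheromatrix run` consumes a sample sheet CSV (`spheroid_id, cell_line,
condition, timepoint_h, modality, path`) and writes one tidy metrics CSV
plus a JSON report per spheroid, including qc flags for any stage that
aborted.

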