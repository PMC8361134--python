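"""Detection and measurement of bead-free voids ("holes") near spheroids.

At late timepoints the matrix around a spheroid can rupture, leaving
voids that carry neither beads nor the diffuse gel fluorescence.  Per
z-slice, candidate dark regions are seeded by a low-intensity percentile
of the extraspheroidal area, their boundaries refined at the local
half-height between the void floor and the surrounding matrix level, and
kept only if (a) their boundary is supported by Canny edges, (b) they
touch or lie within ``hole_max_gap_um`` of the spheroid boundary (holes
form near spheroids; distal dark patches are flagged and ignored),
(c) they exceed a minimum area, and (d) they are genuinely bead-free —
localized beads inside a candidate above a density cutoff veto it.

Hole volume is the sum of per-slice areas times the z-step; the 2D hole
size is the area at the z-slice where it is maximal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import canny
from skimage.morphology import disk

from .errors import ParameterError
from .pipeline_io import AnalysisConfig


@dataclass
class HoleMeasurement:
    """Per-slice hole areas plus the derived 2D and 3D measures.

    Invariants: volume = Σ(area × z_step); max_area = max per-slice area;
    ties for the max-area slice resolve to the lowest slice index.
    """

    slice_indices: list
    areas_um2: list
    z_step_um: float

    def __post_init__(self) -> None:
        if self.z_step_um <= 0:
            raise ParameterError("z_step must be > 0")
        if any(a < 0 for a in self.areas_um2):
            raise ParameterError("hole areas must be >= 0")

    @property
    def volume_um3(self) -> float:
        return float(sum(self.areas_um2)) * self.z_step_um

    @property
    def max_area_um2(self) -> float:
        return max(self.areas_um2, default=0.0)

    @property
    def max_area_slice(self) -> int | None:
        if not self.areas_um2:
            return None
        order = sorted(zip(self.slice_indices, self.areas_um2),
                       key=lambda t: t[0])
        best = max(order, key=lambda t: t[1])  # max() keeps the first tie
        return int(best[0])

    @property
    def n_slices(self) -> int:
        return int(sum(a > 0 for a in self.areas_um2))

    def to_dict(self) -> dict:
        return {
            "slice_indices": [int(i) for i in self.slice_indices],
            "areas_um2": [float(a) for a in self.areas_um2],
            "z_step_um": float(self.z_step_um),
            "volume_um3": self.volume_um3,
            "max_area_um2": float(self.max_area_um2),
            "max_area_slice": self.max_area_slice,
            "n_slices": self.n_slices,
        }


def segment_holes_slice(
    bead_slice: np.ndarray,
    spheroid_mask: np.ndarray | None,
    config: AnalysisConfig | None = None,
    pixel_size: float = 1.0,
    detections: Sequence | None = None,
    adjacency_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float, list]:
    """Segment hole regions in one bead-channel z-slice.

    Returns ``(mask, area_um2, qc_flags)``.  Zero area (empty mask) is a
    valid outcome.  When the spheroid is absent from this slice the
    adjacency constraint is skipped (the hole may extend past the
    spheroid's axial extent).
    """
    if config is None:
        config = AnalysisConfig()
    img = np.asarray(bead_slice, dtype=float)
    flags: list[str] = []
    if spheroid_mask is None:
        spheroid_mask = np.zeros(img.shape, dtype=bool)
    exterior = ~np.asarray(spheroid_mask, dtype=bool)
    empty = np.zeros(img.shape, dtype=bool)
    if not exterior.any():
        return empty, 0.0, flags

    smooth = ndimage.gaussian_filter(img, config.hole_smooth_sigma)
    seed_thr = np.percentile(smooth[exterior], config.hole_dark_percentile)
    seeds = exterior & (smooth < seed_thr)
    lab, n = ndimage.label(seeds)
    if n == 0:
        return empty, 0.0, flags

    min_px = config.hole_min_area_um2 / pixel_size**2
    # Canny support map for boundary validation; the coarse sigma smooths
    # away individual bead spots so the hole rim is the dominant edge
    edges = canny(img, sigma=config.hole_canny_sigma,
                  low_threshold=config.canny_low_q,
                  high_threshold=config.canny_high_q, use_quantiles=True)
    edges_near = ndimage.binary_dilation(edges, structure=disk(3))
    if adjacency_mask is None:
        adjacency_mask = spheroid_mask
    if adjacency_mask.any():
        sph_dist_um = ndimage.distance_transform_edt(
            ~adjacency_mask, sampling=pixel_size
        )
    else:
        sph_dist_um = None

    sizes = np.bincount(lab.ravel(), minlength=n + 1)
    candidates = [i for i in range(1, n + 1)
                  if sizes[i] >= max(min_px * 0.25, 4)]
    final = np.zeros(img.shape, dtype=bool)
    for i in candidates:
        comp = lab == i
        if (final & comp).any():
            continue
        # half-height refinement between the void floor and the slice-wide
        # matrix level (a local halo median is unreliable when the halo is
        # dominated by bright bead light)
        ref = exterior & ~comp
        matrix_level = float(np.median(smooth[ref])) if ref.any() \
            else float(np.median(smooth[exterior]))
        floor = np.median(smooth[comp])
        if floor > config.hole_depth_ratio * matrix_level:
            # not dark enough to be a void (shallow dip in gel texture)
            continue
        local_thr = 0.5 * (floor + matrix_level)
        cand = exterior & (smooth < local_thr)
        cand_lab, _ = ndimage.label(cand)
        hit = np.unique(cand_lab[comp])
        hit = hit[hit > 0]
        if hit.size == 0:
            continue
        region = np.isin(cand_lab, hit)
        if region.sum() < min_px:
            continue
        # the refined region must itself be dark — a shallow seed's
        # half-height threshold can percolate through gel texture into a
        # large bright web, which this rejects
        if float(np.median(smooth[region])) \
                > config.hole_depth_ratio * matrix_level:
            flags.append("hole_refinement_unstable")
            continue
        boundary = region & ~ndimage.binary_erosion(region)
        if boundary.any() and (boundary & edges_near).sum() / boundary.sum() \
                < config.hole_edge_support:
            flags.append("hole_boundary_unsupported")
            continue
        if sph_dist_um is not None and \
                float(sph_dist_um[region].min()) > config.hole_max_gap_um:
            flags.append("distal_void_ignored")
            continue
        if detections:
            pos = np.asarray([d.position_um for d in detections], dtype=float)
            py = np.clip(np.round(pos[:, -2] / pixel_size).astype(int),
                         0, img.shape[0] - 1)
            px = np.clip(np.round(pos[:, -1] / pixel_size).astype(int),
                         0, img.shape[1] - 1)
            n_inside = int(region[py, px].sum())
            if n_inside / (region.sum() * pixel_size**2) \
                    > config.hole_bead_veto_per_um2:
                flags.append("bead_rich_region_vetoed")
                continue
        final |= region

    # de-duplicate components merged by refinement
    return final, float(final.sum()) * pixel_size**2, sorted(set(flags))


def segment_holes_stack(
    bead_stack: np.ndarray,
    geometry,
    config: AnalysisConfig | None = None,
    pixel_size: float = 1.0,
    detections: Sequence | None = None,
) -> tuple[list[np.ndarray], list[tuple[int, float]], list]:
    """Segment holes across a whole z-stack with z-hysteresis.

    First pass: strict per-slice segmentation.  Near the axial caps of a
    void the slice is thin and out-of-focus light from beads just above
    and below raises its floor, so the per-slice depth gate rejects it.
    Second pass: the confidently segmented slices establish the void's
    true floor intensity; the hole is then grown into adjacent slices,
    restricted to dark components that overlap an accepted neighbor mask
    (a void is axially contiguous).  Returns (masks, per-slice (z, area)
    pairs, qc flags).
    """
    if config is None:
        config = AnalysisConfig()
    stack = np.asarray(bead_stack, dtype=float)
    nz = stack.shape[0]
    present = (geometry.slice_present if geometry is not None
               and getattr(geometry, "slice_present", None) is not None
               else None)
    masks, areas, all_flags = [], [], []
    for z in range(nz):
        sph = geometry.slice_mask(z) if geometry is not None else None
        adj = None
        if sph is not None and not sph.any() and present is not None \
                and present.any():
            # spheroid absent from this slice: test hole adjacency against
            # the nearest segmented slice (the void is axially contiguous
            # with the spheroid's 3D footprint)
            near = int(np.flatnonzero(present)[
                np.abs(np.flatnonzero(present) - z).argmin()
            ])
            adj = geometry.slice_mask(near)
        dets_z = None
        if detections is not None:
            dets_z = [d for d in detections if d.frame == z]
        m, a, fl = segment_holes_slice(stack[z], sph, config,
                                       pixel_size=pixel_size,
                                       detections=dets_z,
                                       adjacency_mask=adj)
        masks.append(m)
        areas.append(a)
        all_flags.extend(f"{f}_z{z}" for f in fl)

    accepted = [z for z in range(nz) if areas[z] > 0]
    if accepted:
        global_floor = float(np.median(np.concatenate(
            [stack[z][masks[z]] for z in accepted]
        )))
        min_px = config.hole_min_area_um2 / pixel_size**2
        grown = True
        while grown:
            grown = False
            for z in range(nz):
                if areas[z] > 0:
                    continue
                seed = np.zeros(stack.shape[1:], dtype=bool)
                for zz in (z - 1, z + 1):
                    if 0 <= zz < nz and areas[zz] > 0:
                        seed |= masks[zz]
                if not seed.any():
                    continue
                sph = (geometry.slice_mask(z) if geometry is not None
                       else np.zeros(stack.shape[1:], dtype=bool))
                exterior = ~sph
                smooth = ndimage.gaussian_filter(stack[z],
                                                 config.hole_smooth_sigma)
                ref = exterior & ~seed
                matrix_level = float(np.median(smooth[ref])) if ref.any() \
                    else float(np.median(smooth))
                if matrix_level <= global_floor:
                    continue
                thr = 0.5 * (global_floor + matrix_level)
                cand = exterior & (smooth < thr)
                cl, _ = ndimage.label(cand)
                hit = np.unique(cl[seed & cand])
                hit = hit[hit > 0]
                if hit.size == 0:
                    continue
                region = np.isin(cl, hit)
                if region.sum() < min_px:
                    continue
                if region.sum() > 2 * seed.sum():
                    # axial growth should taper, not balloon; a large jump
                    # means the threshold leaked into gel texture
                    all_flags.append(f"hole_growth_rejected_z{z}")
                    continue
                masks[z] = region
                areas[z] = float(region.sum()) * pixel_size**2
                all_flags.append(f"hole_grown_axially_z{z}")
                grown = True
    per_slice = [(z, areas[z]) for z in range(nz)]
    return masks, per_slice, sorted(set(all_flags))


def hole_volume(
    per_slice: Sequence[tuple[int, float]], z_step: float
) -> HoleMeasurement:
    """Integrate per-slice hole areas into a volume (area × z-step sum)."""
    if z_step <= 0:
        raise ParameterError("z_step must be > 0")
    indices = [int(i) for i, _ in per_slice]
    areas = [float(a) for _, a in per_slice]
    if any(a < 0 for a in areas):
        raise ParameterError("hole areas must be >= 0")
    return HoleMeasurement(slice_indices=indices, areas_um2=areas,
                           z_step_um=z_step)


def max_area_slice(per_slice: Sequence[tuple[int, float]]) -> tuple[int, float]:
    """Slice index with the maximum hole area; ties resolve to the lowest
    slice index."""
    if not per_slice:
        raise ParameterError("per_slice list is empty")
    ordered = sorted(per_slice, key=lambda t: t[0])
    best = max(ordered, key=lambda t: t[1])
    return int(best[0]), float(best[1])


def manual_trace_areas(path, pixel_size: float = 1.0) -> list[tuple[int, float]]:
    """Import manually traced hole outlines from a ROI CSV for comparison
    with the automated measurement.

    Expected columns: ``slice``, ``roi_id``, ``x_um``, ``y_um`` (polygon
    vertices in order).  Returns per-slice summed polygon areas (µm²) via
    the shoelace formula.
    """
    df = pd.read_csv(path)
    needed = {"slice", "roi_id", "x_um", "y_um"}
    if not needed <= set(df.columns):
        raise ParameterError(f"ROI CSV needs columns {sorted(needed)}")
    out: dict[int, float] = {}
    for (z, _), grp in df.groupby(["slice", "roi_id"]):
        x = grp["x_um"].to_numpy()
        y = grp["y_um"].to_numpy()
        area = 0.5 * abs(float(np.dot(x, np.roll(y, -1))
                               - np.dot(y, np.roll(x, -1))))
        out[int(z)] = out.get(int(z), 0.0) + area
    return sorted(out.items())
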