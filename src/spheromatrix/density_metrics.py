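"""Radial collagen-density metrics.

2D densification is the mean bead-channel intensity in the 0–100 µm
annulus around the spheroid edge, expressed as a fold change over hour 0.
The persistence profile bins intensity into 30 µm rings out to 240 µm and
normalizes by the outermost (210–240 µm) ring, so the profile is
invariant to global brightness.  3D density assigns localized beads to
spherical shells around the spheroid centroid, anchored at the estimated
spheroid radius, and divides summed bead intensity by analytic shell
volume (boundary-clipped shells get a Monte-Carlo-corrected volume).
Ring/shell membership is half-open [lo, hi) so every pixel/bead belongs
to exactly one bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyRingError, ParameterError, SegmentationError
from .pipeline_io import AnalysisConfig
from .spheroid_segmentation import DistanceField, distance_map


@dataclass
class RadialProfile:
    """Ring-binned intensity vs distance from the spheroid edge (µm)."""

    ring_edges_um: np.ndarray  # length n+1
    mean_intensity: np.ndarray
    normalized: np.ndarray
    n_pixels: np.ndarray
    coverage: np.ndarray | None = None  # fraction of nominal ring area in view
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        edges = np.asarray(self.ring_edges_um, dtype=float)
        d = {
            "ring_lo_um": edges[:-1].tolist(),
            "ring_hi_um": edges[1:].tolist(),
            "mean_intensity": [float(v) for v in self.mean_intensity],
            "normalized": [float(v) for v in self.normalized],
            "n_pixels": [int(v) for v in self.n_pixels],
            "flags": list(self.flags),
        }
        if self.coverage is not None:
            d["coverage"] = [float(v) for v in self.coverage]
        return d

    def to_dataframe(self) -> pd.DataFrame:
        d = self.to_dict()
        d.pop("flags")
        return pd.DataFrame(d)


@dataclass
class ShellDensityProfile:
    """Bead density in spherical shells around the spheroid centroid.

    ``shell_edges_um`` are absolute distances from the centroid; the grid
    is anchored at the spheroid radius ``r_um`` (edge distance d maps to
    radius r_um + d).  Density = summed integrated bead intensity / shell
    volume (intensity·µm⁻³).
    """

    shell_edges_um: np.ndarray
    densities: np.ndarray
    n_beads: np.ndarray
    r_um: float
    volumes_um3: np.ndarray | None = None

    @staticmethod
    def shell_volume_um3(r_in: float, r_out: float) -> float:
        if not 0 <= r_in < r_out:
            raise ParameterError("need 0 <= r_in < r_out")
        return 4.0 / 3.0 * np.pi * (r_out**3 - r_in**3)

    def shell_index_for_edge_distance(self, d_um: float) -> int:
        """Index of the shell containing radius r_um + d_um."""
        radius = self.r_um + d_um
        edges = np.asarray(self.shell_edges_um)
        i = int(np.searchsorted(edges, radius, side="right") - 1)
        if i < 0 or i >= len(edges) - 1:
            raise ParameterError(
                f"distance {d_um} µm from the edge falls outside the shell grid"
            )
        return i

    def to_dataframe(self) -> pd.DataFrame:
        edges = np.asarray(self.shell_edges_um, dtype=float)
        return pd.DataFrame({
            "shell_lo_um": edges[:-1], "shell_hi_um": edges[1:],
            "density": self.densities, "n_beads": self.n_beads,
        })


@dataclass(frozen=True)
class FoldChange:
    """A ratio of a metric at a later time to a baseline (1 = no change)."""

    value: float
    numerator_time_h: float
    denominator_time_h: float = 0.0
    normalization: tuple = ("hour0",)

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value <= 0:
            raise ParameterError(f"fold change must be finite and > 0: {self.value}")


def ring_mean_intensity(
    bead_image: np.ndarray,
    dfield: DistanceField,
    ring: tuple[float, float],
) -> float:
    """Mean pixel intensity over the ring [lo, hi) µm from the spheroid
    edge; spheroid-interior pixels are excluded."""
    lo, hi = ring
    if not lo < hi:
        raise ParameterError(f"ring lo must be < hi: {ring}")
    img = np.asarray(bead_image, dtype=float)
    if img.shape != dfield.distances_um.shape:
        raise ParameterError("image and distance field shapes differ")
    sel = (~dfield.interior) & (dfield.distances_um >= lo) & (
        dfield.distances_um < hi
    )
    if not sel.any():
        raise EmptyRingError(f"empty_ring [{lo}, {hi}) µm")
    return float(img[sel].mean())


def density2d_series(
    bead_frames: np.ndarray,
    geometries: Sequence,
    config: AnalysisConfig | None = None,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
) -> list[FoldChange]:
    """Per-frame 0–100 µm ring intensity normalized to hour 0.

    The spheroid is re-segmented each frame, so the annulus follows the
    (possibly contracting) spheroid.  The hour-0 entry is identically 1.
    """
    if config is None:
        config = AnalysisConfig()
    frames = np.asarray(bead_frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ParameterError("need a (T, Y, X) array with T >= 2")
    if len(geometries) != frames.shape[0]:
        raise ParameterError("one geometry per frame required")
    if geometries[0] is None:
        raise SegmentationError("segmentation_failed",
                                "hour-0 segmentation unavailable")
    means = []
    for t in range(frames.shape[0]):
        geom = geometries[t] if geometries[t] is not None else geometries[t - 1]
        dfield = distance_map(geom, frames[t].shape, pixel_size=pixel_size,
                              anchor=config.ring_anchor)
        means.append(ring_mean_intensity(frames[t], dfield, config.annulus))
    base = means[0]
    if base <= 0:
        raise ParameterError("hour-0 ring intensity is not positive")
    return [
        FoldChange(value=m / base, numerator_time_h=t * frame_interval)
        for t, m in enumerate(means)
    ]


def persistence_profile(
    bead_image: np.ndarray,
    dfield: DistanceField,
    config: AnalysisConfig | None = None,
    pixel_size: float = 1.0,
) -> RadialProfile:
    """Intensity vs distance in 30 µm rings, normalized by the outermost
    (210–240 µm) reference ring.

    Rings clipped by the field of view are kept but annotated with their
    coverage fraction; rings below 25% nominal coverage are flagged.
    """
    if config is None:
        config = AnalysisConfig()
    edges = np.arange(0.0, config.outer_ref_ring[1] + config.ring_width / 2,
                      config.ring_width)
    img = np.asarray(bead_image, dtype=float)
    means, n_pixels = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (~dfield.interior) & (dfield.distances_um >= lo) & (
            dfield.distances_um < hi
        )
        n_pixels.append(int(sel.sum()))
        means.append(float(img[sel].mean()) if sel.any() else np.nan)
    ref_lo, ref_hi = config.outer_ref_ring
    ref_idx = int(np.flatnonzero(np.isclose(edges[:-1], ref_lo))[0])
    if n_pixels[ref_idx] == 0:
        raise EmptyRingError(
            f"reference ring [{ref_lo}, {ref_hi}) µm is empty"
        )
    ref = means[ref_idx]
    if ref <= 0:
        raise EmptyRingError("reference ring mean intensity is not positive")
    normalized = np.asarray(means) / ref

    r_eq = float(np.sqrt(dfield.interior.sum() * pixel_size**2 / np.pi))
    nominal = np.pi * ((r_eq + edges[1:]) ** 2 - (r_eq + edges[:-1]) ** 2)
    coverage = np.asarray(n_pixels) * pixel_size**2 / nominal
    flags = [
        f"ring_{lo:g}_{hi:g}um_low_coverage"
        for lo, hi, cov in zip(edges[:-1], edges[1:], coverage)
        if cov < 0.25
    ]
    return RadialProfile(
        ring_edges_um=edges, mean_intensity=np.asarray(means),
        normalized=normalized, n_pixels=np.asarray(n_pixels),
        coverage=coverage, flags=flags,
    )


def _clip_fraction_mc(
    r_in: float, r_out: float, centroid_um: np.ndarray,
    box_hi_um: np.ndarray, rng: np.random.Generator, n_samples: int,
) -> float:
    """Monte Carlo fraction of a spherical shell inside the image box."""
    u = rng.uniform(size=n_samples)
    radii = (u * (r_out**3 - r_in**3) + r_in**3) ** (1.0 / 3.0)
    v = rng.normal(size=(n_samples, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = centroid_um + radii[:, None] * v
    inside = np.all((pts >= 0) & (pts <= box_hi_um), axis=1)
    return float(inside.mean())


def shell_density_3d(
    detections: Sequence,
    centroid_um: tuple,
    r: float,
    config: AnalysisConfig | None = None,
    shell_width: float | None = None,
    extent: float | None = None,
    image_shape: tuple | None = None,
    pixel_size: float = 1.0,
    z_step: float = 1.0,
) -> ShellDensityProfile:
    """Bead density per spherical shell from radius ``r`` outward.

    Each shell's density is the sum of the integrated intensities of the
    beads whose centers fall in it, divided by the analytic shell volume
    4/3·π·(r_out³ − r_in³); shells clipped by the image boundary have
    their volume reduced by a fixed-seed Monte Carlo clipped fraction.
    ``shell_density_mode="per_bead_mean"`` divides by the bead count
    instead of summing before the volume division.
    """
    if config is None:
        config = AnalysisConfig()
    width = shell_width if shell_width is not None else config.shell_width_3d
    span = extent if extent is not None else config.shell_extent_3d
    if width <= 0 or span <= 0 or r < 0:
        raise ParameterError("need shell_width > 0, extent > 0, r >= 0")
    c = np.asarray(centroid_um, dtype=float)
    box_hi = None
    if image_shape is not None:
        nz, ny, nx = image_shape
        box_hi = np.asarray([(nz - 1) * z_step, (ny - 1) * pixel_size,
                             (nx - 1) * pixel_size])
        if np.any(c < 0) or np.any(c > box_hi):
            raise ParameterError(f"centroid {tuple(c)} outside the image box")
    n_shells = int(np.ceil(span / width))
    edges = r + width * np.arange(n_shells + 1)

    pos = np.asarray([d.position_um for d in detections], dtype=float).reshape(-1, 3)
    masses = np.asarray([d.mass for d in detections], dtype=float)
    dist = np.linalg.norm(pos - c, axis=1) if len(pos) else np.empty(0)

    rng = np.random.default_rng([int(config.rng_seed) % (2**31), 90021])
    densities, n_beads, volumes = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dist >= lo) & (dist < hi)
        vol = ShellDensityProfile.shell_volume_um3(lo, hi)
        if box_hi is not None:
            fully_inside = np.all(c - hi >= 0) and np.all(c + hi <= box_hi)
            if not fully_inside:
                frac = _clip_fraction_mc(lo, hi, c, box_hi, rng,
                                         config.mc_samples)
                vol *= frac
        n = int(sel.sum())
        if vol <= 0:
            densities.append(0.0)
        elif config.shell_density_mode == "per_bead_mean" and n > 0:
            densities.append(float(masses[sel].mean()) / vol)
        else:
            densities.append(float(masses[sel].sum()) / vol)
        n_beads.append(n)
        volumes.append(vol)
    return ShellDensityProfile(
        shell_edges_um=edges, densities=np.asarray(densities),
        n_beads=np.asarray(n_beads), r_um=float(r),
        volumes_um3=np.asarray(volumes),
    )


def density3d_fold_change(
    profile_t0: ShellDensityProfile,
    profile_t6: ShellDensityProfile,
    config: AnalysisConfig | None = None,
) -> FoldChange:
    """3D density fold change read 25 µm away from the spheroid edge.

    Each profile uses the shell containing its *own* r + 25 µm, so the
    query stays well-defined when the spheroid radius differs between the
    two timepoints.
    """
    if config is None:
        config = AnalysisConfig()
    off = config.shell_offset_3d
    i0 = profile_t0.shell_index_for_edge_distance(off)
    i6 = profile_t6.shell_index_for_edge_distance(off)
    if profile_t0.n_beads[i0] == 0 or profile_t6.n_beads[i6] == 0:
        raise EmptyRingError(
            f"shell at {off} µm from the edge contains no beads"
        )
    d0 = profile_t0.densities[i0]
    if d0 <= 0:
        raise EmptyRingError("hour-0 shell density is not positive")
    return FoldChange(
        value=float(profile_t6.densities[i6] / d0),
        numerator_time_h=config.fold_change_hour,
    )


def normalize_to_reference_group(
    values: Sequence, reference: Sequence
) -> list[float]:
    """Divide each value by the arithmetic mean of the reference group —
    the cross-condition normalization used to absorb inter-patient
    heterogeneity (reference = the TGF-β-only group of the same line)."""
    def _as_float(v):
        return float(v.value) if isinstance(v, FoldChange) else float(v)

    ref = [_as_float(v) for v in reference]
    if not ref:
        raise ParameterError("reference group is empty")
    mean = float(np.mean(ref))
    if mean == 0:
        raise ParameterError("reference group mean is zero")
    return [_as_float(v) / mean for v in values]
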