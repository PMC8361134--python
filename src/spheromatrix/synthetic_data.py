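"""Synthetic spheroid-in-gel image generator with exact ground truth.

Emulates the phenomena the analysis pipeline quantifies: a bright,
roughly circular spheroid; point-like fiducial beads in the surrounding
gel; inward radial bead advection that decays with distance and time
(collagen pulling); bead accumulation at the spheroid boundary
(densification, emergent rather than painted); and, optionally, a
bead-free ellipsoidal void adjacent to the spheroid (hole formation).

Advection operates on continuous bead positions; rendering discretizes
afterward, so the stored ground truth is exact, not pixel-quantized.
The bead channel carries a diffuse ``matrix_background`` level wherever
gel exists (absent inside the spheroid and inside holes), emulating the
out-of-focus fluorescence of a bead-laden gel in a confocal section; this
is what makes voids appear as dark regions, as they do in real data.

All outputs are bit-reproducible from ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import integrate

from .errors import ParameterError
from .pipeline_io import AcquisitionMetadata, ImageStack

_ADVECTION_SUBSTEPS = 5


@dataclass(frozen=True)
class HoleSpec:
    """Ellipsoidal bead-free void: center (z, y, x) µm, semi-axes (a, b, c) µm
    with a, b lateral (x, y) and c axial (z)."""

    center_um: tuple[float, float, float]
    semiaxes_um: tuple[float, float, float]

    def contains(self, pos_zyx_um: np.ndarray) -> np.ndarray:
        z0, y0, x0 = self.center_um
        a, b, c = self.semiaxes_um
        p = np.atleast_2d(pos_zyx_um)
        q = ((p[:, 2] - x0) / a) ** 2 + ((p[:, 1] - y0) / b) ** 2 + (
            (p[:, 0] - z0) / c
        ) ** 2
        return q <= 1.0

    def slice_area_um2(self, z_um: float) -> float:
        """Analytic cross-section area at axial position z (µm²)."""
        z0 = self.center_um[0]
        a, b, c = self.semiaxes_um
        f = 1.0 - ((z_um - z0) / c) ** 2
        return math.pi * a * b * f if f > 0 else 0.0

    @property
    def volume_um3(self) -> float:
        a, b, c = self.semiaxes_um
        return 4.0 / 3.0 * math.pi * a * b * c


@dataclass
class SimulationParams:
    """Study conditions of the simulated assay.

    Defaults reflect the imaging setup the pipeline targets: a ~120 µm
    diameter spheroid in a 512×512 µm field at 1 µm/px, 13 half-hour
    frames (hours 0–6) for timelapses, 5 µm z-steps for volumes, and a
    pulling field v(d, t) = v0·exp(−d/L)·exp(−t/τ) with v0 = 3 µm/h at
    the spheroid edge, spatial decay L = 100 µm and temporal decay
    τ = 6 h, matching the observed decrease of bead speed with time and
    of densification with distance.
    """

    image_shape: tuple[int, int] = (512, 512)  # (ny, nx) pixels
    pixel_size: float = 1.0  # µm / px
    z_step: float = 5.0  # µm
    n_slices: int = 40
    n_frames: int = 13
    frame_interval: float = 0.5  # h
    spheroid_radius: float = 60.0  # µm
    spheroid_center_um: tuple | None = None  # (y, x) or (z, y, x); default center
    n_beads: int = 2000
    bead_psf_sigma: float = 1.5  # px, lateral
    bead_psf_sigma_z: float = 2.5  # µm, axial
    bead_intensity_mean: float = 200.0
    bead_intensity_sd: float = 20.0
    background: float = 10.0
    noise_sd: float = 2.0
    matrix_background: float = 30.0
    cell_intensity: float = 200.0
    pull_speed_v0: float = 3.0  # µm/h at the spheroid edge
    pull_decay_length: float = 100.0  # µm (np.inf = no spatial decay)
    pull_decay_time: float = 6.0  # h (np.inf = no temporal decay)
    surface_bead_fraction: float = 0.05  # beads stuck at the spheroid surface (3D)
    densify_amplitude: float = 0.0  # direct density-profile mode (3D)
    densify_length: float = 30.0  # µm
    hole: HoleSpec | None = None
    edge_clearance: float = 0.5  # µm; beads never sit closer to the surface
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beads < 0:
            raise ParameterError("n_beads must be >= 0")
        for name in ("pixel_size", "z_step", "frame_interval", "spheroid_radius",
                     "bead_psf_sigma", "bead_psf_sigma_z", "densify_length"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        ny, nx = self.image_shape
        cy, cx = self.center_2d_um
        r = self.spheroid_radius
        if (cy - r < 0 or cx - r < 0 or cy + r > (ny - 1) * self.pixel_size
                or cx + r > (nx - 1) * self.pixel_size):
            raise ParameterError("spheroid does not fit inside the image")
        if self.hole is not None:
            z0, y0, x0 = self.hole.center_um
            a, b, c = self.hole.semiaxes_um
            zmax = (self.n_slices - 1) * self.z_step
            if (x0 - a < 0 or x0 + a > (nx - 1) * self.pixel_size
                    or y0 - b < 0 or y0 + b > (ny - 1) * self.pixel_size
                    or z0 - c < 0 or z0 + c > zmax):
                raise ParameterError("hole ellipsoid intersects the image boundary")

    @property
    def center_2d_um(self) -> tuple[float, float]:
        if self.spheroid_center_um is not None:
            c = self.spheroid_center_um
            return (float(c[-2]), float(c[-1]))
        ny, nx = self.image_shape
        return ((ny - 1) * self.pixel_size / 2.0, (nx - 1) * self.pixel_size / 2.0)

    @property
    def center_3d_um(self) -> tuple[float, float, float]:
        if self.spheroid_center_um is not None and len(self.spheroid_center_um) == 3:
            return tuple(float(v) for v in self.spheroid_center_um)
        cy, cx = self.center_2d_um
        return ((self.n_slices - 1) * self.z_step / 2.0, cy, cx)

    def density_factor(self, d_um):
        """Relative bead density vs distance from the spheroid edge."""
        return 1.0 + self.densify_amplitude * np.exp(
            -np.asarray(d_um, dtype=float) / self.densify_length
        )


@dataclass
class GroundTruth:
    """Exact simulated state backing every metric's expected value."""

    params: SimulationParams
    bead_positions_um: np.ndarray  # (T, n, 2) timelapse or (n, 3) z-stack, (y,x)/(z,y,x)
    bead_amplitudes: np.ndarray
    spheroid_center_um: tuple
    spheroid_radius_um: float
    hole: HoleSpec | None = None
    time_h: float = 0.0

    def edge_distance(self, pos: np.ndarray) -> np.ndarray:
        """Distance from the spheroid edge (µm, negative inside)."""
        c = np.asarray(self.spheroid_center_um, dtype=float)
        p = np.atleast_2d(pos)
        return np.linalg.norm(p - c, axis=-1) - self.spheroid_radius_um

    # ---- timelapse queries -------------------------------------------------
    def mean_speed_in_annulus(
        self, annulus: tuple[float, float] = (0.0, 100.0)
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-interval mean bead speed (µm/h) for beads starting in the
        annulus, plus the number contributing."""
        pos = self.bead_positions_um
        if pos.ndim != 3:
            raise ParameterError("mean_speed_in_annulus requires a timelapse truth")
        dt = self.params.frame_interval
        lo, hi = annulus
        means, ns = [], []
        for t in range(pos.shape[0] - 1):
            d = self.edge_distance(pos[t])
            sel = (d >= lo) & (d < hi)
            step = np.linalg.norm(pos[t + 1][sel] - pos[t][sel], axis=1)
            ns.append(int(sel.sum()))
            means.append(float(np.mean(step) / dt) if sel.any() else np.nan)
        return np.asarray(means), np.asarray(ns)

    def ring_intensity_ratio(
        self, frame: int, ring: tuple[float, float] = (0.0, 100.0)
    ) -> float:
        """Noise-free mean bead-channel intensity in the ring at ``frame``
        divided by that at frame 0 (the expected 2D density fold change)."""
        p = self.params
        img_t = _render_bead_plane(self.bead_positions_um[frame],
                                   self.bead_amplitudes, p)
        img_0 = _render_bead_plane(self.bead_positions_um[0],
                                   self.bead_amplitudes, p)
        ny, nx = p.image_shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        cy, cx = self.spheroid_center_um
        d = (np.hypot(yy * p.pixel_size - cy, xx * p.pixel_size - cx)
             - self.spheroid_radius_um)
        sel = (d >= ring[0]) & (d < ring[1])
        base = p.background + p.matrix_background
        return float((img_t[sel].mean() + base) / (img_0[sel].mean() + base))

    # ---- z-stack queries ---------------------------------------------------
    def _density_normalization(self, n_samples: int = 200_000) -> float:
        """Mean of the relative density factor over the sampled domain.

        The generator places a *fixed* number of beads, so a radial
        enhancement f(d) rescales the realized density to f(d)/Z with
        Z = <f> over the domain (box minus spheroid minus hole).  Z is
        estimated by fixed-seed Monte Carlo over that domain.
        """
        p = self.params
        if p.densify_amplitude == 0:
            return 1.0
        rng = np.random.default_rng([int(p.rng_seed) % (2**31), 424242])
        ny, nx = p.image_shape
        lims = np.array([(p.n_slices - 1) * p.z_step,
                         (ny - 1) * p.pixel_size, (nx - 1) * p.pixel_size])
        pts = rng.uniform(size=(n_samples, 3)) * lims
        d = (np.linalg.norm(pts - np.asarray(self.spheroid_center_um), axis=1)
             - self.spheroid_radius_um)
        keep = d > p.edge_clearance
        if self.hole is not None:
            keep &= ~self.hole.contains(pts)
        return float(np.mean(p.density_factor(np.clip(d[keep], 0, None))))

    def expected_shell_density_factor(self, d_lo: float, d_hi: float) -> float:
        """Expected realized density in a shell [d_lo, d_hi) µm from the
        spheroid edge, relative to a uniform field of the same bead count:
        the volume-weighted mean of f(d) over the shell (shells grow as
        (R+d)²), divided by the fixed-count normalization <f>."""
        R = self.spheroid_radius_um
        f = self.params.density_factor
        num = integrate.quad(lambda d: f(d) * (R + d) ** 2, d_lo, d_hi)[0]
        den = integrate.quad(lambda d: (R + d) ** 2, d_lo, d_hi)[0]
        return (num / den) / self._density_normalization()

    def count_in_hole(self) -> int:
        if self.hole is None:
            return 0
        return int(self.hole.contains(self.bead_positions_um).sum())


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _add_gaussian_spots(
    img: np.ndarray,
    pos_px: np.ndarray,
    amps: np.ndarray,
    sigma_px: float,
) -> None:
    """Accumulate isotropic Gaussian spots into ``img`` in place."""
    ny, nx = img.shape
    w = int(math.ceil(4 * sigma_px))
    for (py, px_), a in zip(pos_px, amps):
        if a <= 0:
            continue
        y0, y1 = int(math.floor(py)) - w, int(math.floor(py)) + w + 1
        x0, x1 = int(math.floor(px_)) - w, int(math.floor(px_)) + w + 1
        y0c, y1c = max(y0, 0), min(y1, ny)
        x0c, x1c = max(x0, 0), min(x1, nx)
        if y0c >= y1c or x0c >= x1c:
            continue
        ys = np.arange(y0c, y1c) - py
        xs = np.arange(x0c, x1c) - px_
        g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma_px**2))
        img[y0c:y1c, x0c:x1c] += a * g


def render_beads(
    positions_um: np.ndarray | Sequence,
    params: SimulationParams,
    amplitudes: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render 2D bead positions (µm) as Gaussian spots of sigma
    ``bead_psf_sigma`` px on a uniform background with additive Gaussian
    noise (``noise_sd``), clipped at zero."""
    positions_um = np.asarray(positions_um, dtype=float).reshape(-1, 2)
    if not np.isfinite(positions_um).all():
        raise ParameterError("bead positions must be finite")
    if amplitudes is None:
        amplitudes = np.full(len(positions_um), params.bead_intensity_mean)
    img = np.full(params.image_shape, float(params.background))
    _add_gaussian_spots(img, positions_um / params.pixel_size,
                        np.asarray(amplitudes, dtype=float),
                        params.bead_psf_sigma)
    if params.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(params.rng_seed)
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def _render_bead_plane(positions_um, amps, params: SimulationParams) -> np.ndarray:
    """Noise-free, zero-background bead spot image (µm positions)."""
    img = np.zeros(params.image_shape)
    _add_gaussian_spots(img, np.asarray(positions_um) / params.pixel_size,
                        np.asarray(amps, dtype=float), params.bead_psf_sigma)
    return img


def _disk_mask(params: SimulationParams, center_um, radius_um) -> np.ndarray:
    ny, nx = params.image_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = center_um
    return (np.hypot(yy * params.pixel_size - cy, xx * params.pixel_size - cx)
            <= radius_um)


def _render_cell_plane(params: SimulationParams, center_um, radius_um,
                       rng: np.random.Generator) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    img = params.cell_intensity * _disk_mask(params, center_um, radius_um)
    img = gaussian_filter(img.astype(float), 2.0) + params.background
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def _sample_beads_2d(params: SimulationParams, rng) -> np.ndarray:
    """Uniform bead positions (µm) in the field, outside the spheroid."""
    ny, nx = params.image_shape
    cy, cx = params.center_2d_um
    rmin = params.spheroid_radius + params.edge_clearance
    out = np.empty((0, 2))
    while len(out) < params.n_beads:
        n = max(params.n_beads - len(out), 16)
        cand = rng.uniform(0, 1, size=(2 * n, 2))
        cand[:, 0] *= (ny - 1) * params.pixel_size
        cand[:, 1] *= (nx - 1) * params.pixel_size
        keep = np.hypot(cand[:, 0] - cy, cand[:, 1] - cx) > rmin
        out = np.vstack([out, cand[keep]])
    return out[: params.n_beads]


def pull_speed(params: SimulationParams, d_um, t_h) -> np.ndarray:
    """Advection speed v(d, t) = v0 · exp(−d/L) · exp(−t/τ) (µm/h)."""
    d = np.clip(np.asarray(d_um, dtype=float), 0.0, None)
    with np.errstate(over="ignore"):
        sp = np.where(np.isinf(params.pull_decay_length), 1.0,
                      np.exp(-d / params.pull_decay_length))
        tp = (1.0 if np.isinf(params.pull_decay_time)
              else math.exp(-t_h / params.pull_decay_time))
    return params.pull_speed_v0 * sp * tp


def simulate_timelapse(params: SimulationParams) -> tuple[ImageStack, GroundTruth]:
    """Simulate a 2-channel timelapse of a spheroid pulling beads inward.

    Beads advect radially toward the spheroid center with speed
    v(d, t) = v0·exp(−d/L)·exp(−t/τ) at distance d from the spheroid edge
    and accumulate at the boundary, producing emergent densification.
    """
    if params.n_frames < 2:
        raise ParameterError("timelapse needs n_frames >= 2")
    rng = np.random.default_rng(params.rng_seed)
    c = np.asarray(params.center_2d_um)
    pos = _sample_beads_2d(params, rng)
    amps = np.clip(
        rng.normal(params.bead_intensity_mean, params.bead_intensity_sd,
                   size=params.n_beads),
        0.1 * params.bead_intensity_mean, None,
    )
    dt_sub = params.frame_interval / _ADVECTION_SUBSTEPS
    all_pos = [pos.copy()]
    t_h = 0.0
    for _ in range(params.n_frames - 1):
        for _ in range(_ADVECTION_SUBSTEPS):
            rel = pos - c
            dist = np.linalg.norm(rel, axis=1)
            d = dist - params.spheroid_radius
            v = pull_speed(params, d, t_h)
            step = np.minimum(v * dt_sub,
                              np.clip(d - params.edge_clearance, 0.0, None))
            pos = pos - (step / np.maximum(dist, 1e-12))[:, None] * rel
            t_h += dt_sub
        all_pos.append(pos.copy())
    positions = np.stack(all_pos)

    frames = []
    for t in range(params.n_frames):
        bead = np.clip(
            params.background + params.matrix_background
            + _render_bead_plane(positions[t], amps, params)
            + (rng.normal(0.0, params.noise_sd, size=params.image_shape)
               if params.noise_sd > 0 else 0.0),
            0.0, None,
        )
        cell = _render_cell_plane(params, c, params.spheroid_radius, rng)
        frames.append(np.stack([cell, bead]))
    pixels = np.stack(frames)  # (T, C, Y, X)
    meta = AcquisitionMetadata(
        pixel_size=params.pixel_size,
        frame_interval=params.frame_interval,
        channel_roles={"cell": 0, "bead": 1},
    )
    stack = ImageStack(pixels=pixels, axes="TCYX", metadata=meta)
    truth = GroundTruth(
        params=params, bead_positions_um=positions, bead_amplitudes=amps,
        spheroid_center_um=tuple(c), spheroid_radius_um=params.spheroid_radius,
    )
    return stack, truth


def _sample_beads_3d(params: SimulationParams, rng) -> np.ndarray:
    """Bead positions (z, y, x) µm outside the spheroid (and hole), with
    relative density 1 + A·exp(−d/L) vs distance from the spheroid edge."""
    ny, nx = params.image_shape
    czyx = np.asarray(params.center_3d_um)
    rmin = params.spheroid_radius + params.edge_clearance
    fmax = float(params.density_factor(0.0))
    n_surface = int(round(params.surface_bead_fraction * params.n_beads))
    n_bulk = params.n_beads - n_surface

    out = np.empty((0, 3))
    lims = np.array([(params.n_slices - 1) * params.z_step,
                     (ny - 1) * params.pixel_size,
                     (nx - 1) * params.pixel_size])
    while len(out) < n_bulk:
        n = max(n_bulk - len(out), 64)
        cand = rng.uniform(0, 1, size=(2 * n, 3)) * lims
        d = np.linalg.norm(cand - czyx, axis=1) - params.spheroid_radius
        keep = d > params.edge_clearance
        if params.hole is not None:
            keep &= ~params.hole.contains(cand)
        accept = rng.uniform(0, 1, size=len(cand)) < (
            params.density_factor(np.clip(d, 0, None)) / fmax
        )
        out = np.vstack([out, cand[keep & accept]])
    bulk = out[:n_bulk]

    if n_surface > 0:
        surf = np.empty((0, 3))
        while len(surf) < n_surface:
            u = rng.normal(size=(2 * n_surface, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            cand = czyx + (params.spheroid_radius + params.edge_clearance) * u
            keep = np.all((cand >= 0) & (cand <= lims), axis=1)
            if params.hole is not None:
                keep &= ~params.hole.contains(cand)
            surf = np.vstack([surf, cand[keep]])
        return np.vstack([bulk, surf[:n_surface]])
    return bulk


def simulate_zstack(
    params: SimulationParams, time_label_h: float = 0.0
) -> tuple[ImageStack, GroundTruth]:
    """Simulate a 2-channel z-stack of a spheroid in a bead-laden gel.

    Beads are placed uniformly (or with the radial density profile of
    ``densify_amplitude``/``densify_length``) outside a spherical spheroid;
    a fraction sit at the spheroid surface, producing the density spike
    used for radius estimation.  An optional ellipsoidal hole excludes
    beads and matrix background.
    """
    if params.n_slices < 2:
        raise ParameterError("z-stack needs n_slices >= 2")
    rng = np.random.default_rng(params.rng_seed)
    czyx = np.asarray(params.center_3d_um)
    pos = _sample_beads_3d(params, rng)
    amps = np.clip(
        rng.normal(params.bead_intensity_mean, params.bead_intensity_sd,
                   size=len(pos)),
        0.1 * params.bead_intensity_mean, None,
    )

    ny, nx = params.image_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    yy_um = yy * params.pixel_size
    xx_um = xx * params.pixel_size
    slices = []
    R = params.spheroid_radius
    for z in range(params.n_slices):
        z_um = z * params.z_step
        # matrix occupancy: outside the spheroid cross-section and the hole
        dz2 = (z_um - czyx[0]) ** 2
        matrix = np.ones(params.image_shape, dtype=bool)
        if dz2 < R**2:
            r_slice = math.sqrt(R**2 - dz2)
            matrix &= np.hypot(yy_um - czyx[1], xx_um - czyx[2]) > r_slice
        if params.hole is not None:
            z0, y0, x0 = params.hole.center_um
            a, b, cax = params.hole.semiaxes_um
            f = 1.0 - ((z_um - z0) / cax) ** 2
            if f > 0:
                inside = (((xx_um - x0) / a) ** 2 + ((yy_um - y0) / b) ** 2) <= f
                matrix &= ~inside
        bead = params.background + params.matrix_background * matrix.astype(float)

        dz = pos[:, 0] - z_um
        wz = np.exp(-(dz**2) / (2 * params.bead_psf_sigma_z**2))
        vis = wz > 0.01
        _add_gaussian_spots(
            bead, pos[vis][:, 1:] / params.pixel_size, amps[vis] * wz[vis],
            params.bead_psf_sigma,
        )
        if params.noise_sd > 0:
            bead += rng.normal(0.0, params.noise_sd, size=bead.shape)
        bead = np.clip(bead, 0.0, None)

        if dz2 < R**2:
            r_slice = math.sqrt(R**2 - dz2)
            cell = _render_cell_plane(params, (czyx[1], czyx[2]), r_slice, rng)
        else:
            cell = np.clip(
                params.background
                + (rng.normal(0.0, params.noise_sd, size=params.image_shape)
                   if params.noise_sd > 0 else 0.0),
                0.0, None)
        slices.append(np.stack([cell, bead]))

    pixels = np.stack(slices)  # (Z, C, Y, X)
    meta = AcquisitionMetadata(
        pixel_size=params.pixel_size, z_step=params.z_step,
        channel_roles={"cell": 0, "bead": 1},
    )
    stack = ImageStack(pixels=pixels, axes="ZCYX", metadata=meta)
    truth = GroundTruth(
        params=params, bead_positions_um=pos, bead_amplitudes=amps,
        spheroid_center_um=tuple(czyx), spheroid_radius_um=R,
        hole=params.hole, time_h=time_label_h,
    )
    return stack, truth


def simulate_hole_stack(params: SimulationParams) -> tuple[ImageStack, GroundTruth]:
    """Simulate a late-timepoint z-stack containing a bead-free void.

    Ground truth carries the analytic per-slice areas
    π·a·b·(1 − (z−z0)²/c²) and the analytic volume 4/3·π·a·b·c.
    """
    if params.hole is None:
        raise ParameterError("simulate_hole_stack requires params.hole")
    return simulate_zstack(params, time_label_h=120.0)


def radial_intensity_image(
    image_shape: tuple[int, int],
    pixel_size: float,
    center_um: tuple[float, float],
    radius_um: float,
    profile: Callable[[np.ndarray], np.ndarray],
    interior_value: float | None = None,
) -> np.ndarray:
    """Deterministic image whose intensity is ``profile(d)`` of the distance
    d (µm) from a disk edge — a direct-gradient mode for testing radial
    metrics against closed forms."""
    ny, nx = image_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    d = (np.hypot(yy * pixel_size - center_um[0], xx * pixel_size - center_um[1])
         - radius_um)
    img = np.asarray(profile(np.clip(d, 0.0, None)), dtype=float)
    if interior_value is not None:
        img = np.where(d < 0, interior_value, img)
    return np.clip(img, 0.0, None)
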