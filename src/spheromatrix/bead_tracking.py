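"""Bead localization, linking and peri-spheroid speed.

Localization follows the classic centroid scheme for colloid tracking:
band-pass filtering (small-scale Gaussian smoothing minus a boxcar
background), local-maxima candidates above a percentile threshold, and
iterative intensity-weighted centroid refinement to sub-pixel precision.
Linking solves, per frame pair, the globally optimal assignment that
minimizes summed squared displacement with a fixed cost for unmatched
detections (birth/death) — no gap closing.  The speed metric averages
per-step bead speeds over the 0–100 µm annulus around the spheroid edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .errors import ParameterError
from .pipeline_io import AnalysisConfig
from .spheroid_segmentation import SpheroidGeometry, distance_map

_UNLINKABLE = 1e18


@dataclass(frozen=True)
class BeadDetection:
    """A localized bead: position in µm ((y, x) or (z, y, x)), the frame or
    slice it came from, integrated intensity (mass) and peak intensity."""

    position_um: tuple
    frame: int
    mass: float
    peak: float


@dataclass
class Trajectory:
    """Linked bead positions over time."""

    id: int
    points: list = field(default_factory=list)  # (frame, position_um) pairs

    def add(self, frame: int, position_um: tuple) -> None:
        if self.points and frame <= self.points[-1][0]:
            raise ParameterError("trajectory frames must be strictly increasing")
        self.points.append((frame, tuple(position_um)))

    def __len__(self) -> int:
        return len(self.points)

    @property
    def steps_um(self) -> np.ndarray:
        """Per-step displacement vectors (µm)."""
        pos = np.asarray([p for _, p in self.points], dtype=float)
        return np.diff(pos, axis=0)


@dataclass
class SpeedSeries:
    """Mean bead speed (µm/h) per frame interval in the annulus; ``speeds``
    entries are ``None`` where no step contributed (flagged, not zero)."""

    times_h: list
    speeds: list
    n_beads: list
    flags: list = field(default_factory=list)


def _bandpass(img: np.ndarray, feature_diameter: int) -> np.ndarray:
    smooth = ndimage.gaussian_filter(img, 1.0)
    background = ndimage.uniform_filter(img, feature_diameter)
    return np.clip(smooth - background, 0.0, None)


def _refine_centroid(bp: np.ndarray, y: int, x: int, w: int) -> tuple:
    """Iterative intensity-weighted centroid in a (2w+1)² window."""
    ny, nx = bp.shape
    cy, cx = float(y), float(x)
    for _ in range(3):
        iy, ix = int(round(cy)), int(round(cx))
        y0, y1 = max(iy - w, 0), min(iy + w + 1, ny)
        x0, x1 = max(ix - w, 0), min(ix + w + 1, nx)
        win = bp[y0:y1, x0:x1]
        tot = win.sum()
        if tot <= 0:
            return cy, cx, 0.0
        ys = np.arange(y0, y1)
        xs = np.arange(x0, x1)
        ny_c = float((win.sum(axis=1) * ys).sum() / tot)
        nx_c = float((win.sum(axis=0) * xs).sum() / tot)
        if abs(ny_c - cy) < 1e-4 and abs(nx_c - cx) < 1e-4:
            cy, cx = ny_c, nx_c
            break
        cy, cx = ny_c, nx_c
    return cy, cx, float(tot)


def detect_beads(
    image: np.ndarray,
    config: AnalysisConfig | None = None,
    pixel_size: float = 1.0,
    exclude_mask: np.ndarray | None = None,
    frame: int = 0,
) -> list[BeadDetection]:
    """Localize beads in a single-channel image to sub-pixel precision.

    Detections whose centers fall inside ``exclude_mask`` (e.g. the
    spheroid) are discarded.  Returns an empty list when nothing is found.
    """
    if config is None:
        config = AnalysisConfig()
    d = int(config.feature_diameter)
    if d < 3 or d % 2 == 0:
        raise ParameterError("feature_diameter must be odd and >= 3")
    img = np.asarray(image, dtype=float)
    bp = _bandpass(img, d)
    positive = bp[bp > 0]
    if positive.size == 0:
        return []
    # percentile threshold plus a robust noise floor (median of the
    # half-normal positive tail estimates sigma); both scale with the
    # image, keeping detection invariant to uniform intensity rescaling
    sigma_est = float(np.median(positive)) / 0.6745
    thr = max(np.percentile(positive, config.detect_percentile),
              config.detect_snr * sigma_est)
    maxima = (ndimage.maximum_filter(bp, size=d) == bp) & (bp > thr)
    w = d // 2
    cands = []
    for y, x in np.argwhere(maxima):
        cy, cx, mass = _refine_centroid(bp, y, x, w)
        if mass <= 0 or mass < config.min_mass:
            continue
        if not (0 <= cy <= img.shape[0] - 1 and 0 <= cx <= img.shape[1] - 1):
            continue
        if exclude_mask is not None and exclude_mask[
            int(round(cy)), int(round(cx))
        ]:
            continue
        cands.append(
            BeadDetection(
                position_um=(cy * pixel_size, cx * pixel_size),
                frame=frame, mass=mass, peak=float(bp[y, x]),
            )
        )
    if not cands:
        return []
    # band-pass ringing around bright spots leaves faint spurious maxima;
    # a relative mass floor removes them without an absolute cutoff
    floor = config.mass_rel_floor * max(c.mass for c in cands)
    return [c for c in cands if c.mass >= floor]


def detect_beads_3d(
    zstack: np.ndarray,
    config: AnalysisConfig | None = None,
    pixel_size: float = 1.0,
    z_step: float = 1.0,
    geometry: SpheroidGeometry | None = None,
) -> list[BeadDetection]:
    """Localize beads in a z-stack: per-slice 2D detection plus a
    mass-weighted z centroid over a 3-slice window.

    Full 3D Gaussian fitting is deliberately avoided — at a 5 µm z-step a
    bead spans at most a few slices, so the slice-merge approach is
    adequate and much cheaper.
    """
    if config is None:
        config = AnalysisConfig()
    stack = np.asarray(zstack, dtype=float)
    per_slice: list[list[BeadDetection]] = []
    for z in range(stack.shape[0]):
        mask = geometry.slice_mask(z) if geometry is not None else None
        per_slice.append(
            detect_beads(stack[z], config, pixel_size=pixel_size,
                         exclude_mask=mask, frame=z)
        )
    rad = config.feature_diameter * pixel_size / 2.0
    flat = [(d.mass, z, i) for z, dets in enumerate(per_slice)
            for i, d in enumerate(dets)]
    flat.sort(key=lambda t: (-t[0], t[1], t[2]))
    used = [np.zeros(len(dets), dtype=bool) for dets in per_slice]
    out = []
    for _, z, i in flat:
        if used[z][i]:
            continue
        anchor = per_slice[z][i]
        group = [(z, anchor)]
        used[z][i] = True
        for dz in (-1, 1):
            zz = z + dz
            if not (0 <= zz < len(per_slice)):
                continue
            for j, cand in enumerate(per_slice[zz]):
                if used[zz][j]:
                    continue
                if np.hypot(
                    cand.position_um[0] - anchor.position_um[0],
                    cand.position_um[1] - anchor.position_um[1],
                ) <= rad:
                    group.append((zz, cand))
                    used[zz][j] = True
                    break
        masses = np.asarray([g.mass for _, g in group])
        zs = np.asarray([zz * z_step for zz, _ in group])
        z_um = float((masses * zs).sum() / masses.sum())
        out.append(
            BeadDetection(
                position_um=(z_um, anchor.position_um[0], anchor.position_um[1]),
                frame=z, mass=float(masses.sum()), peak=anchor.peak,
            )
        )
    return out


def link_detections(
    frames: list[list[BeadDetection]], max_displacement: float
) -> list[Trajectory]:
    """Link detections across frames into trajectories.

    Each frame pair is solved as a global assignment minimizing the summed
    squared displacement, with unmatched detections charged the cost
    ``max_displacement²`` (they terminate or start trajectories).  Ties are
    resolved deterministically by detection index order.
    """
    if max_displacement <= 0:
        raise ParameterError("max_displacement must be > 0")
    if not frames:
        raise ParameterError("need at least one frame")
    b = float(max_displacement) ** 2
    trajectories: list[Trajectory] = []
    current: list[int] = []  # detection index in frame -> trajectory index
    for i, det in enumerate(frames[0]):
        traj = Trajectory(id=len(trajectories))
        traj.add(det.frame, det.position_um)
        trajectories.append(traj)
        current.append(traj.id)

    for t in range(1, len(frames)):
        prev, cur = frames[t - 1], frames[t]
        n1, n2 = len(prev), len(cur)
        nxt = [-1] * n2
        if n1 and n2:
            p1 = np.asarray([d.position_um for d in prev])
            p2 = np.asarray([d.position_um for d in cur])
            d2 = ((p1[:, None, :] - p2[None, :, :]) ** 2).sum(axis=2)
            size = n1 + n2
            cost = np.zeros((size, size))
            cost[:n1, :n2] = np.where(d2 <= b, d2, _UNLINKABLE)
            cost[:n1, n2:] = _UNLINKABLE
            cost[n1:, :n2] = _UNLINKABLE
            cost[np.arange(n1), n2 + np.arange(n1)] = b
            cost[n1 + np.arange(n2), np.arange(n2)] = b
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if r < n1 and c < n2 and d2[r, c] <= b:
                    nxt[c] = current[r]
        new_current = []
        for j, det in enumerate(cur):
            if nxt[j] >= 0:
                trajectories[nxt[j]].add(det.frame, det.position_um)
                new_current.append(nxt[j])
            else:
                traj = Trajectory(id=len(trajectories))
                traj.add(det.frame, det.position_um)
                trajectories.append(traj)
                new_current.append(traj.id)
        current = new_current
    return trajectories


def annulus_speed(
    trajectories: list[Trajectory],
    geometry: SpheroidGeometry | list[SpheroidGeometry],
    config: AnalysisConfig | None = None,
    frame_interval: float = 1.0,
) -> SpeedSeries:
    """Mean bead speed per frame interval in the peri-spheroid annulus.

    A step contributes to interval t if its *start* position lies in the
    annulus (edge distance in [inner, outer)); speed = |Δposition| /
    frame_interval.  Intervals with no contributing step report ``None``
    and a flag.  In ``speed_mode="net"`` each trajectory contributes its
    net displacement over its lifetime divided by that lifetime, assigned
    to its start interval.
    """
    if config is None:
        config = AnalysisConfig()
    if frame_interval <= 0:
        raise ParameterError("frame_interval must be > 0")
    lo, hi = config.annulus

    geoms = geometry if isinstance(geometry, (list, tuple)) else None
    single = geometry if geoms is None else None
    dfields: dict[int, object] = {}

    def dfield_at(t: int):
        g = geoms[min(t, len(geoms) - 1)] if geoms is not None else single
        key = id(g)
        if key not in dfields:
            dfields[key] = (g, distance_map(g, anchor=config.ring_anchor))
        return dfields[key][1], (geoms[min(t, len(geoms) - 1)] if geoms else single)

    def edge_distance(t: int, pos_um: tuple) -> tuple[float, bool]:
        df, g = dfield_at(t)
        iy = int(round(pos_um[-2] / g.pixel_size))
        ix = int(round(pos_um[-1] / g.pixel_size))
        iy = np.clip(iy, 0, df.distances_um.shape[-2] - 1)
        ix = np.clip(ix, 0, df.distances_um.shape[-1] - 1)
        if df.distances_um.ndim == 3:
            iz = int(round(pos_um[0] / g.z_step))
            iz = np.clip(iz, 0, df.distances_um.shape[0] - 1)
            return float(df.distances_um[iz, iy, ix]), bool(df.interior[iz, iy, ix])
        return float(df.distances_um[iy, ix]), bool(df.interior[iy, ix])

    n_intervals = max(
        (fr for traj in trajectories for fr, _ in traj.points), default=0
    )
    sums = np.zeros(n_intervals)
    counts = np.zeros(n_intervals, dtype=int)
    for traj in trajectories:
        pts = traj.points
        if config.speed_mode == "net" and len(pts) >= 2:
            (f0, p0), (f1, p1) = pts[0], pts[-1]
            d, inside = edge_distance(f0, p0)
            if not inside and lo <= d < hi and f0 < n_intervals:
                speed = (np.linalg.norm(np.subtract(p1, p0))
                         / ((f1 - f0) * frame_interval))
                sums[f0] += speed
                counts[f0] += 1
            continue
        for (f0, p0), (f1, p1) in zip(pts, pts[1:]):
            if f1 != f0 + 1 or f0 >= n_intervals:
                continue
            d, inside = edge_distance(f0, p0)
            if inside or not (lo <= d < hi):
                continue
            speed = np.linalg.norm(np.subtract(p1, p0)) / frame_interval
            sums[f0] += speed
            counts[f0] += 1

    speeds, flags = [], []
    for t in range(n_intervals):
        if counts[t] == 0:
            speeds.append(None)
            flags.append(f"no_beads_in_annulus_interval_{t}")
        else:
            speeds.append(float(sums[t] / counts[t]))
    return SpeedSeries(
        times_h=[t * frame_interval for t in range(n_intervals)],
        speeds=speeds, n_beads=list(map(int, counts)), flags=flags,
    )


def detections_to_dataframe(detections: list[BeadDetection]) -> pd.DataFrame:
    rows = []
    for d in detections:
        pos = d.position_um
        row = {"frame": d.frame, "mass": d.mass, "peak": d.peak,
               "y_um": pos[-2], "x_um": pos[-1]}
        if len(pos) == 3:
            row["z_um"] = pos[0]
        rows.append(row)
    return pd.DataFrame(rows)


def trajectories_to_dataframe(trajectories: list[Trajectory]) -> pd.DataFrame:
    rows = []
    for traj in trajectories:
        for fr, pos in traj.points:
            row = {"trajectory_id": traj.id, "frame": fr,
                   "y_um": pos[-2], "x_um": pos[-1]}
            if len(pos) == 3:
                row["z_um"] = pos[0]
            rows.append(row)
    return pd.DataFrame(rows)
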