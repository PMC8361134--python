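"""Stack/report I/O, configuration and per-spheroid orchestration.

The package analyzes fluorescence stacks of a cell spheroid embedded in
bead-labeled collagen.  Arrays are ordered ``(T?, Z?, C, Y, X)`` with absent
axes dropped; every physical distance is expressed in micrometres via
:class:`AcquisitionMetadata`, never in pixels, so results are invariant to
the camera calibration.  Coordinates are 0-based with pixel centers at
integer indices (physical position = index * pixel_size).

TIFF stacks are written as plain multi-page TIFF plus a YAML sidecar
(`<file>.yaml`) holding the axis string and calibration; OME/ImageJ axis
metadata in the TIFF itself is honored when present.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import (
    ConfigurationError,
    ParameterError,
    SegmentationError,
    SpheromatrixError,
)

_AXIS_ORDER = "TZCYX"

SAMPLE_SHEET_COLUMNS = (
    "spheroid_id",
    "cell_line",
    "condition",
    "timepoint_h",
    "modality",
    "path",
)


@dataclass(frozen=True)
class AcquisitionMetadata:
    """Physical calibration of an acquisition.

    Parameters
    ----------
    pixel_size:
        Lateral calibration in µm per pixel. Required and positive.
    z_step:
        Axial spacing in µm between z-slices (z-stacks only).
    frame_interval:
        Time in hours between frames (timelapses only).
    channel_roles:
        Mapping from role name to channel index; must cover at least
        ``{"cell", "bead"}``.
    """

    pixel_size: float
    z_step: float | None = None
    frame_interval: float | None = None
    channel_roles: Mapping[str, int] = field(
        default_factory=lambda: {"cell": 0, "bead": 1}
    )

    def __post_init__(self) -> None:
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise ParameterError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.z_step is not None and self.z_step <= 0:
            raise ParameterError(f"z_step must be > 0, got {self.z_step}")
        if self.frame_interval is not None and self.frame_interval <= 0:
            raise ParameterError(
                f"frame_interval must be > 0, got {self.frame_interval}"
            )
        missing = {"cell", "bead"} - set(self.channel_roles)
        if missing:
            raise ConfigurationError(f"channel_roles missing roles: {sorted(missing)}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "pixel_size": float(self.pixel_size),
            "z_step": None if self.z_step is None else float(self.z_step),
            "frame_interval": (
                None if self.frame_interval is None else float(self.frame_interval)
            ),
            "channel_roles": {k: int(v) for k, v in self.channel_roles.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AcquisitionMetadata":
        return cls(
            pixel_size=d["pixel_size"],
            z_step=d.get("z_step"),
            frame_interval=d.get("frame_interval"),
            channel_roles=dict(d.get("channel_roles", {"cell": 0, "bead": 1})),
        )


@dataclass
class ImageStack:
    """A calibrated multi-channel pixel array.

    ``axes`` is a subsequence of ``"TZCYX"`` naming ``pixels``' dimensions.
    A timelapse has a T axis (T >= 2, frame_interval set); a z-stack has a
    Z axis (Z >= 2, z_step set).
    """

    pixels: np.ndarray
    axes: str
    metadata: AcquisitionMetadata

    def __post_init__(self) -> None:
        ax = self.axes.upper()
        if ax != "".join(c for c in _AXIS_ORDER if c in ax) or len(set(ax)) != len(ax):
            raise ConfigurationError(f"axes {self.axes!r} must be ordered like TZCYX")
        for needed in "CYX":
            if needed not in ax:
                raise ConfigurationError(f"axes {self.axes!r} lack mandatory {needed}")
        if self.pixels.ndim != len(ax):
            raise ConfigurationError(
                f"axes {ax!r} imply {len(ax)} dims but pixels have shape "
                f"{self.pixels.shape}"
            )
        self.axes = ax
        if not np.isfinite(self.pixels).all():
            raise ConfigurationError("pixel intensities must be finite")
        if self.pixels.min() < 0:
            raise ConfigurationError("pixel intensities must be non-negative")
        n_chan = self.pixels.shape[ax.index("C")]
        needed = max(self.metadata.channel_roles.values()) + 1
        if n_chan < needed:
            raise ConfigurationError(
                f"channel_roles need {needed} channels but stack has {n_chan} "
                f"(shape {self.pixels.shape}, axes {ax})"
            )
        if "T" in ax:
            if self.metadata.frame_interval is None:
                raise ConfigurationError("timelapse requires metadata.frame_interval")
            if self.pixels.shape[ax.index("T")] < 2:
                raise ConfigurationError("timelapse requires T >= 2")
        if "Z" in ax:
            if self.metadata.z_step is None:
                raise ConfigurationError("z-stack requires metadata.z_step")
            if self.pixels.shape[ax.index("Z")] < 2:
                raise ConfigurationError("z-stack requires Z >= 2")

    @property
    def is_timelapse(self) -> bool:
        return "T" in self.axes

    @property
    def is_zstack(self) -> bool:
        return "Z" in self.axes

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[self.axes.index("T")] if self.is_timelapse else 1

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[self.axes.index("Z")] if self.is_zstack else 1

    def channel(self, role: str) -> np.ndarray:
        """Return the pixel array for a channel role, C axis removed."""
        if role not in self.metadata.channel_roles:
            raise ConfigurationError(f"unknown channel role {role!r}")
        idx = self.metadata.channel_roles[role]
        return np.take(self.pixels, idx, axis=self.axes.index("C"))


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".yaml")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF with a YAML calibration sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.pixels)
    sidecar = {"axes": stack.axes, "metadata": stack.metadata.to_dict()}
    _sidecar_path(path).write_text(yaml.safe_dump(sidecar))
    return path


def read_stack(
    path: str | Path,
    metadata: AcquisitionMetadata | None = None,
    axes: str | None = None,
) -> ImageStack:
    """Read a TIFF stack back into an :class:`ImageStack`.

    Calibration comes from ``metadata`` if given, else from the YAML sidecar;
    axis layout from ``axes``, the sidecar, or the TIFF's own series metadata,
    in that order.  Absence of calibration is an error — every downstream
    metric depends on it.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            pixels = tf.asarray()
            tiff_axes = tf.series[0].axes if tf.series else None
    except Exception as exc:  # noqa: BLE001 - surface as I/O error
        raise IOError(f"unreadable TIFF {path}: {exc}") from exc

    sidecar: dict[str, Any] = {}
    sc_path = _sidecar_path(path)
    if sc_path.exists():
        sidecar = yaml.safe_load(sc_path.read_text()) or {}

    if metadata is None:
        if "metadata" not in sidecar:
            raise ConfigurationError(
                f"no metadata given and no sidecar found for {path}"
            )
        metadata = AcquisitionMetadata.from_dict(sidecar["metadata"])

    if axes is None:
        axes = sidecar.get("axes")
    if axes is None and tiff_axes and set(tiff_axes) <= set(_AXIS_ORDER):
        axes = tiff_axes
    if axes is None:
        raise ConfigurationError(f"cannot determine axis layout for {path}")
    return ImageStack(pixels=pixels, axes=axes, metadata=metadata)


@dataclass
class AnalysisConfig:
    """All tunable analysis parameters, with the platform's standard defaults.

    Distances are in µm, times in hours.  The fixed distances mirror the
    measurement conventions of the assay: bead speed and 2D density are
    averaged in the 0–100 µm annulus around the spheroid edge, persistence
    profiles use 30 µm rings normalized by the outermost 210–240 µm ring,
    and the 3D density fold change is read 25 µm away from the spheroid edge.
    """

    # annuli / rings / shells
    annulus: tuple[float, float] = (0.0, 100.0)
    ring_width: float = 30.0
    outer_ref_ring: tuple[float, float] = (210.0, 240.0)
    shell_offset_3d: float = 25.0
    shell_width_3d: float = 10.0
    shell_extent_3d: float = 80.0
    spike_shell_width: float = 5.0
    spike_factor: float = 2.0
    ring_anchor: str = "edge"  # or "centroid"
    fold_change_hour: float = 6.0
    focus_slice: int | None = None

    # bead detection / linking
    feature_diameter: int = 7
    min_mass: float = 0.0
    detect_percentile: float = 64.0
    detect_snr: float = 5.0
    mass_rel_floor: float = 0.01
    max_displacement: float = 10.0
    speed_mode: str = "per_step"  # or "net"

    # segmentation
    cv_iterations: int = 200
    cv_tol: float = 1e-3
    cv_smoothing: int = 1
    smooth_sigma: float = 2.0
    canny_sigma: float = 2.0
    canny_low_q: float = 0.50
    canny_high_q: float = 0.90
    min_slice_area_um2: float = 500.0

    # hole quantification
    hole_dark_percentile: float = 20.0
    hole_smooth_sigma: float = 2.0
    hole_canny_sigma: float = 6.0
    hole_depth_ratio: float = 0.5
    hole_min_area_um2: float = 100.0
    hole_max_gap_um: float = 25.0
    hole_edge_support: float = 0.3
    hole_bead_veto_per_um2: float = 1e-3

    # statistics / numerics
    fdr: float = 0.05
    shell_density_mode: str = "sum"  # or "per_bead_mean"
    wilcoxon_zero_policy: str = "drop"  # or "pratt"
    mc_samples: int = 100_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ring_width", "shell_offset_3d", "shell_width_3d",
                     "shell_extent_3d", "spike_shell_width", "max_displacement"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not (0 <= self.annulus[0] < self.annulus[1]):
            raise ParameterError(f"bad annulus {self.annulus}")
        lo, hi = self.outer_ref_ring
        if hi <= lo:
            raise ParameterError(f"outer_ref_ring upper must exceed lower: {lo, hi}")
        n = hi / self.ring_width
        if abs(n - round(n)) > 1e-9:
            raise ParameterError(
                f"ring grid [0, {hi}] must divide evenly by ring_width "
                f"{self.ring_width}"
            )
        if self.ring_anchor not in ("edge", "centroid"):
            raise ParameterError(f"ring_anchor must be edge|centroid")
        if self.speed_mode not in ("per_step", "net"):
            raise ParameterError("speed_mode must be per_step|net")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["annulus"] = list(self.annulus)
        d["outer_ref_ring"] = list(self.outer_ref_ring)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnalysisConfig":
        kw = dict(d)
        if "annulus" in kw:
            kw["annulus"] = tuple(kw["annulus"])
        if "outer_ref_ring" in kw:
            kw["outer_ref_ring"] = tuple(kw["outer_ref_ring"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


@dataclass
class SpheroidReport:
    """All per-spheroid metrics, stored in plain JSON-serializable form.

    ``speed_series`` entries: {"time_h", "speed_um_per_h", "n"};
    ``density2d_series`` entries: {"time_h", "fold_change"};
    ``persistence_profile``: ring grid with mean/normalized intensities;
    ``hole``: per-slice areas, max-area slice and volume.
    """

    spheroid_id: str = ""
    cell_line: str = ""
    condition: str = ""
    speed_series: list[dict[str, Any]] = field(default_factory=list)
    density2d_series: list[dict[str, Any]] = field(default_factory=list)
    persistence_profile: dict[str, Any] | None = None
    density3d_fold_change: float | None = None
    hole: dict[str, Any] | None = None
    qc_flags: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for series, key in (
            (self.speed_series, "time_h"),
            (self.density2d_series, "time_h"),
        ):
            times = [e[key] for e in series]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ParameterError("series times must be strictly increasing")
        for e in self.density2d_series:
            if e["fold_change"] <= 0:
                raise ParameterError("fold changes must be > 0")
        if self.density3d_fold_change is not None and self.density3d_fold_change <= 0:
            raise ParameterError("fold changes must be > 0")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SpheroidReport":
        return cls(**d)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample sheet CSV mapping files to spheroids."""
    df = pd.read_csv(path)
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"sample sheet missing columns {sorted(missing)}")
    return df


def _tidy_rows(report: SpheroidReport) -> list[dict[str, Any]]:
    base = {
        "spheroid_id": report.spheroid_id,
        "cell_line": report.cell_line,
        "condition": report.condition,
    }
    rows = []
    for e in report.speed_series:
        rows.append(base | {"metric": "bead_speed_um_per_h",
                            "timepoint_h": e["time_h"],
                            "value": e["speed_um_per_h"], "n": e["n"]})
    for e in report.density2d_series:
        rows.append(base | {"metric": "density2d_fold_change",
                            "timepoint_h": e["time_h"],
                            "value": e["fold_change"], "n": None})
    if report.persistence_profile is not None:
        prof = report.persistence_profile
        for lo, hi, v in zip(prof["ring_lo_um"], prof["ring_hi_um"],
                             prof["normalized"]):
            rows.append(base | {"metric": f"persistence_norm_{lo:g}_{hi:g}um",
                                "timepoint_h": prof.get("time_h"),
                                "value": v, "n": None})
    if report.density3d_fold_change is not None:
        rows.append(base | {"metric": "density3d_fold_change",
                            "timepoint_h": None,
                            "value": report.density3d_fold_change, "n": None})
    if report.hole is not None:
        rows.append(base | {"metric": "hole_volume_um3", "timepoint_h": None,
                            "value": report.hole["volume_um3"], "n": None})
        rows.append(base | {"metric": "hole_max_area_um2", "timepoint_h": None,
                            "value": report.hole["max_area_um2"], "n": None})
    return rows


def write_report(reports: Sequence[SpheroidReport], out_dir: str | Path) -> dict:
    """Write one tidy CSV over all reports plus one JSON per spheroid.

    Re-reading the JSON reproduces each report bit-exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: list[dict[str, Any]] = []
    json_paths = []
    for rep in reports:
        rows.extend(_tidy_rows(rep))
        p = out_dir / f"{rep.spheroid_id or 'spheroid'}.json"
        p.write_text(json.dumps(rep.to_dict(), indent=1))
        json_paths.append(p)
    columns = ["spheroid_id", "cell_line", "condition", "metric",
               "timepoint_h", "value", "n"]
    csv_path = out_dir / "metrics.csv"
    pd.DataFrame(rows, columns=columns).to_csv(csv_path, index=False)
    return {"csv": csv_path, "json": json_paths}


def read_report(path: str | Path) -> SpheroidReport:
    return SpheroidReport.from_dict(json.loads(Path(path).read_text()))


def run_pipeline(
    stack_2d: ImageStack | None = None,
    stack_3d_t0: ImageStack | None = None,
    stack_3d_t6: ImageStack | None = None,
    stack_3d_day5: ImageStack | None = None,
    config: AnalysisConfig | None = None,
    spheroid_id: str = "",
    cell_line: str = "",
    condition: str = "",
) -> SpheroidReport:
    """Run the full per-spheroid analysis over whichever stacks are present.

    2D timelapse -> bead speed series, 2D density fold changes, persistence
    profile; paired t0/t6 z-stacks -> 3D density fold change; late z-stack
    -> hole measurement.  Stages that abort record a qc flag instead of
    raising, mirroring the manual-verification step of the original
    workflow: nothing is excluded silently.
    """
    from . import bead_tracking as bt
    from . import density_metrics as dm
    from . import hole_quantification as hq
    from . import spheroid_segmentation as seg

    if config is None:
        config = AnalysisConfig()
    report = SpheroidReport(
        spheroid_id=spheroid_id, cell_line=cell_line, condition=condition
    )
    qc = report.qc_flags

    if stack_2d is not None:
        cell = stack_2d.channel("cell")
        bead = stack_2d.channel("bead")
        dt = stack_2d.metadata.frame_interval
        ps = stack_2d.metadata.pixel_size
        geoms: list = []
        for t in range(stack_2d.n_frames):
            try:
                geoms.append(seg.segment_spheroid_2d(cell[t], config, pixel_size=ps))
            except SegmentationError:
                geoms.append(None)
                qc.append(f"segmentation_failed_frame_{t}")
        if geoms[0] is None:
            qc.append("segmentation_failed")
        else:
            for t in range(len(geoms)):  # reuse last good geometry
                if geoms[t] is None:
                    geoms[t] = geoms[t - 1]
            frames = [
                bt.detect_beads(bead[t], config, pixel_size=ps,
                                exclude_mask=geoms[t].mask, frame=t)
                for t in range(stack_2d.n_frames)
            ]
            if sum(len(f) for f in frames) == 0:
                qc.append("no_beads_detected")
            else:
                trajs = bt.link_detections(frames, config.max_displacement)
                speed = bt.annulus_speed(trajs, geoms, config, frame_interval=dt)
                report.speed_series = [
                    {"time_h": float(t), "speed_um_per_h": v, "n": int(n)}
                    for t, v, n in zip(speed.times_h, speed.speeds, speed.n_beads)
                    if v is not None
                ]
            try:
                fcs = dm.density2d_series(bead, geoms, config, pixel_size=ps,
                                          frame_interval=dt)
                report.density2d_series = [
                    {"time_h": fc.numerator_time_h, "fold_change": fc.value}
                    for fc in fcs
                ]
            except SegmentationError as exc:
                qc.append(exc.flag)
            except SpheromatrixError:
                qc.append("density2d_failed")
            t_idx = min(
                range(stack_2d.n_frames),
                key=lambda t: abs(t * dt - config.fold_change_hour),
            )
            try:
                dfield = seg.distance_map(geoms[t_idx], bead[t_idx].shape,
                                          pixel_size=ps,
                                          anchor=config.ring_anchor)
                prof = dm.persistence_profile(bead[t_idx], dfield, config)
                report.persistence_profile = prof.to_dict() | {
                    "time_h": t_idx * dt
                }
            except Exception:  # noqa: BLE001 - qc-flagged, not fatal
                qc.append("persistence_profile_failed")

    profiles = {}
    for label, stack in (("t0", stack_3d_t0), ("t6", stack_3d_t6)):
        if stack is None:
            continue
        try:
            profiles[label] = _zstack_density_profile(stack, config, qc, label)
        except SegmentationError as exc:
            qc.append(f"{exc.flag}_{label}")
        except SpheromatrixError:
            qc.append(f"zstack_profile_failed_{label}")
    if "t0" in profiles and "t6" in profiles:
        try:
            fc = dm.density3d_fold_change(profiles["t0"], profiles["t6"], config)
            report.density3d_fold_change = fc.value
        except Exception:  # noqa: BLE001
            qc.append("density3d_fold_change_failed")

    if stack_3d_day5 is not None:
        try:
            report.hole = _measure_holes(stack_3d_day5, config, qc)
        except SegmentationError as exc:
            qc.append(f"{exc.flag}_day5")
        except SpheromatrixError:
            qc.append("hole_measurement_failed")

    report.validate()
    return report


def _zstack_density_profile(stack, config, qc, label):
    from . import bead_tracking as bt
    from . import density_metrics as dm
    from . import spheroid_segmentation as seg

    ps = stack.metadata.pixel_size
    zs = stack.metadata.z_step
    geom = seg.segment_spheroid_3d(stack.channel("cell"), config,
                                   pixel_size=ps, z_step=zs)
    det = bt.detect_beads_3d(stack.channel("bead"), config,
                             pixel_size=ps, z_step=zs, geometry=geom)
    if not det:
        qc.append(f"no_beads_detected_{label}")
    # Radius from the density spike at the spheroid surface, falling back to
    # the segmentation-derived equivalent radius when no spike qualifies.
    spike_prof = dm.shell_density_3d(
        det, geom.centroid_um, r=0.0, config=config,
        shell_width=config.spike_shell_width,
        extent=geom.equivalent_radius_um + config.shell_extent_3d,
        image_shape=stack.channel("bead").shape, pixel_size=ps, z_step=zs,
    )
    try:
        r = seg.estimate_radius_from_profile(spike_prof, config)
    except SegmentationError:
        r = geom.equivalent_radius_um
        qc.append(f"no_spike_found_{label}")
    return dm.shell_density_3d(
        det, geom.centroid_um, r=r, config=config,
        image_shape=stack.channel("bead").shape, pixel_size=ps, z_step=zs,
    )


def _measure_holes(stack, config, qc):
    from . import bead_tracking as bt
    from . import hole_quantification as hq
    from . import spheroid_segmentation as seg

    ps = stack.metadata.pixel_size
    zs = stack.metadata.z_step
    geom = seg.segment_spheroid_3d(stack.channel("cell"), config,
                                   pixel_size=ps, z_step=zs)
    bead = stack.channel("bead")
    det = bt.detect_beads_3d(bead, config, pixel_size=ps, z_step=zs,
                             geometry=geom)
    _, per_slice, flags = hq.segment_holes_stack(
        bead, geom, config, pixel_size=ps, detections=det
    )
    qc.extend(flags)
    meas = hq.hole_volume(per_slice, zs)
    return meas.to_dict()
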