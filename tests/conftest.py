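"""Shared fixtures: expensive synthetic scenes are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

import spheromatrix as sm


@pytest.fixture(scope="session")
def config():
    return sm.AnalysisConfig()


@pytest.fixture(scope="session")
def const_pull_timelapse():
    """500 beads pulled inward at a constant 3 µm/h (no spatial or temporal
    decay), 13 half-hour frames — the canonical speed-recovery scene."""
    params = sm.SimulationParams(
        n_beads=500, pull_speed_v0=3.0,
        pull_decay_length=np.inf, pull_decay_time=np.inf, rng_seed=1,
    )
    return params, *sm.simulate_timelapse(params)


@pytest.fixture(scope="session")
def static_timelapse():
    """Same scene with the pulling switched off (v0 = 0)."""
    params = sm.SimulationParams(n_beads=500, pull_speed_v0=0.0, rng_seed=3)
    return params, *sm.simulate_timelapse(params)


@pytest.fixture(scope="session")
def uniform_zstack_10k():
    """Uniform bead field around a spherical spheroid, 10^4 beads."""
    params = sm.SimulationParams(
        image_shape=(300, 300), n_slices=40, n_beads=10_000,
        spheroid_radius=50.0, surface_bead_fraction=0.0, rng_seed=5,
    )
    return params, *sm.simulate_zstack(params)


@pytest.fixture(scope="session")
def clean_spheroid_zstack(config):
    """Rendered sphere (r = 50 µm, z-step 5 µm) plus its 3D segmentation."""
    params = sm.SimulationParams(
        image_shape=(300, 300), n_slices=40, n_beads=6000,
        spheroid_radius=50.0, rng_seed=5,
    )
    stack, truth = sm.simulate_zstack(params)
    geom = sm.segment_spheroid_3d(
        stack.channel("cell"), config,
        pixel_size=params.pixel_size, z_step=params.z_step,
    )
    return params, stack, truth, geom


def make_hole_scene(z_step: float, n_slices: int, seed: int = 7):
    """Ellipsoidal void (40, 40, 30 µm) beside a 50 µm spheroid."""
    hole = sm.HoleSpec(
        center_um=((n_slices - 1) * z_step / 2.0, 127.5, 215.0),
        semiaxes_um=(40.0, 40.0, 30.0),
    )
    params = sm.SimulationParams(
        image_shape=(256, 256), n_slices=n_slices, z_step=z_step,
        n_beads=8000, spheroid_radius=50.0, hole=hole, rng_seed=seed,
    )
    return params, *sm.simulate_hole_stack(params)


@pytest.fixture(scope="session")
def hole_measurements(config):
    """Hole measurement at z-steps 10, 5, 2.5 µm on the same void."""
    from spheromatrix import hole_quantification as hq

    out = {}
    for z_step, n_slices in ((10.0, 15), (5.0, 30), (2.5, 60)):
        params, stack, truth = make_hole_scene(z_step, n_slices)
        geom = sm.segment_spheroid_3d(stack.channel("cell"), config,
                                      z_step=z_step)
        _, per_slice, flags = hq.segment_holes_stack(
            stack.channel("bead"), geom, config
        )
        meas = hq.hole_volume(per_slice, z_step)
        out[z_step] = {"params": params, "truth": truth, "meas": meas,
                       "flags": flags, "n_slices": n_slices}
    return out


@pytest.fixture(scope="session")
def densification_scene(config):
    """Paired t0 (uniform) / t6 (densified) z-stacks with shell profiles."""
    from spheromatrix import pipeline_io as pio

    common = dict(image_shape=(300, 300), n_slices=40, n_beads=8000,
                  spheroid_radius=50.0)
    s0, t0 = sm.simulate_zstack(sm.SimulationParams(rng_seed=21, **common), 0.0)
    s6, t6 = sm.simulate_zstack(
        sm.SimulationParams(rng_seed=22, densify_amplitude=1.5,
                            densify_length=30.0, **common), 6.0)
    qc: list[str] = []
    prof0 = pio._zstack_density_profile(s0, config, qc, "t0")
    prof6 = pio._zstack_density_profile(s6, config, qc, "t6")
    return {"stack_t0": s0, "stack_t6": s6, "truth_t0": t0, "truth_t6": t6,
            "profile_t0": prof0, "profile_t6": prof6, "qc": qc}


@pytest.fixture(scope="session")
def null_fdr_rate():
    """Empirical FDR of the Wilcoxon-vs-1 + BH family procedure over 2000
    all-null replicates (m = 8 log-normal fold-change groups, n = 10)."""
    from spheromatrix import group_statistics as gs

    rng = np.random.default_rng(2024)
    m, n = 8, 10
    fdp = []
    for _ in range(2000):
        groups = {f"g{i}": np.exp(rng.normal(0, 0.2, n)) for i in range(m)}
        res = gs.fold_change_family(groups, fdr=0.05)
        rejected = sum(r.p_adjusted <= 0.05 for r in res.values())
        fdp.append(0.0 if rejected == 0 else 1.0)  # all nulls: V/R is 0 or 1
    return float(np.mean(fdp))


@pytest.fixture(scope="session")
def emergent_2d_series(config):
    """Emergent 2D densification: measured fold-change series vs the
    render-based ground-truth ring-intensity ratios."""
    from spheromatrix import density_metrics as dm

    params = sm.SimulationParams(n_beads=2000, rng_seed=11)
    stack, truth = sm.simulate_timelapse(params)
    cell, bead = stack.channel("cell"), stack.channel("bead")
    geoms = [sm.segment_spheroid_2d(cell[t], config)
             for t in range(stack.n_frames)]
    fcs = dm.density2d_series(bead, geoms, config,
                              frame_interval=params.frame_interval)
    gt = [truth.ring_intensity_ratio(t) for t in range(stack.n_frames)]
    return {"params": params, "stack": stack, "truth": truth,
            "geoms": geoms, "fold_changes": fcs, "gt_ratios": gt}
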