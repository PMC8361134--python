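"""Ring and shell density metrics against per-pixel and closed-form
oracles."""

import numpy as np
import pytest
from scipy import integrate

import spheromatrix as sm
from spheromatrix import density_metrics as dm
from spheromatrix.bead_tracking import BeadDetection
from spheromatrix.errors import EmptyRingError, ParameterError
from _oracles import poisson_weighted_slope_t, ring_mean_oracle


def _disk_field(shape=(128, 128), radius=20.0, pixel_size=1.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    c = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    mask = np.hypot(yy - c[0], xx - c[1]) * pixel_size <= radius
    geom = sm.SpheroidGeometry(mask=mask, pixel_size=pixel_size)
    return geom, sm.distance_map(geom), c


class TestRingMeanIntensity:
    def test_uniform_image_returns_constant(self, config):
        _, dfield, _ = _disk_field()
        img = np.full((128, 128), 3.7)
        for ring in [(0, 30), (10, 40), (0, 100)]:
            assert dm.ring_mean_intensity(img, dfield, ring) == \
                pytest.approx(3.7, abs=1e-12)

    def test_ring_outside_image_is_empty(self):
        _, dfield, _ = _disk_field()
        with pytest.raises(EmptyRingError):
            dm.ring_mean_intensity(np.ones((128, 128)), dfield, (500, 600))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_pixel_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        _, dfield, _ = _disk_field(radius=rng.uniform(10, 30))
        img = rng.uniform(0, 100, (128, 128))
        lo = rng.uniform(0, 20)
        hi = lo + rng.uniform(5, 40)
        assert dm.ring_mean_intensity(img, dfield, (lo, hi)) == \
            ring_mean_oracle(img, dfield, lo, hi)


class TestDensity2DSeries:
    def test_identical_frames_all_unity(self, config):
        geom, _, _ = _disk_field()
        frames = np.tile(np.random.default_rng(0).uniform(1, 9, (128, 128)),
                         (4, 1, 1))
        fcs = dm.density2d_series(frames, [geom] * 4, config,
                                  frame_interval=0.5)
        assert [fc.value for fc in fcs] == [1.0] * 4

    def test_doubled_intensity_gives_fold_change_two(self, config):
        geom, _, _ = _disk_field()
        base = np.random.default_rng(1).uniform(1, 9, (128, 128))
        fcs = dm.density2d_series(np.stack([base, 2 * base]), [geom, geom],
                                  config, frame_interval=1.0)
        assert fcs[1].value == pytest.approx(2.0)

    def test_missing_hour0_geometry_aborts(self, config):
        geom, _, _ = _disk_field()
        frames = np.ones((3, 128, 128))
        with pytest.raises(sm.SegmentationError):
            dm.density2d_series(frames, [None, geom, geom], config)

    def test_emergent_densification_monotone_and_matches_truth(
        self, emergent_2d_series
    ):
        meas = [fc.value for fc in emergent_2d_series["fold_changes"]]
        gt = emergent_2d_series["gt_ratios"]
        assert all(b >= a - 1e-6 for a, b in zip(meas, meas[1:]))
        assert meas[-1] == pytest.approx(gt[-1], rel=0.10)

    def test_fold_change_invariant_to_intensity_scaling(self, config):
        geom, _, _ = _disk_field()
        rng = np.random.default_rng(2)
        frames = rng.uniform(1, 9, (3, 128, 128))
        a = [fc.value for fc in dm.density2d_series(frames, [geom] * 3,
                                                    config)]
        b = [fc.value for fc in dm.density2d_series(5.5 * frames, [geom] * 3,
                                                    config)]
        assert a == pytest.approx(b, rel=1e-12)


class TestPersistenceProfile:
    def test_uniform_image_all_unity(self, config):
        _, dfield, _ = _disk_field(shape=(600, 600), radius=40.0)
        prof = dm.persistence_profile(np.full((600, 600), 9.0), dfield,
                                      config)
        assert np.allclose(prof.normalized, 1.0)
        assert prof.normalized[-1] == 1.0

    def test_reference_ring_is_identically_one(self, config):
        _, dfield, _ = _disk_field(shape=(600, 600), radius=40.0)
        rng = np.random.default_rng(0)
        prof = dm.persistence_profile(rng.uniform(5, 10, (600, 600)),
                                      dfield, config)
        assert prof.normalized[-1] == 1.0

    def test_exponential_gradient_decreasing_within_five_percent(
        self, config
    ):
        """L = 60 µm exponential decay: strictly decreasing normalized
        profile, each ring within 5% of the area-weighted closed form."""
        R, L = 60.0, 60.0
        shape, c = (640, 640), (319.5, 319.5)
        img = sm.radial_intensity_image(
            shape, 1.0, c, R, lambda d: 40.0 + 160.0 * np.exp(-d / L)
        )
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        geom = sm.SpheroidGeometry(
            mask=np.hypot(yy - c[0], xx - c[1]) <= R, pixel_size=1.0
        )
        prof = dm.persistence_profile(img, sm.distance_map(geom), config)
        assert all(b < a for a, b in zip(prof.normalized, prof.normalized[1:]))

        def ring_mean(lo, hi):
            num = integrate.quad(
                lambda d: (40 + 160 * np.exp(-d / L)) * (R + d), lo, hi)[0]
            den = integrate.quad(lambda d: R + d, lo, hi)[0]
            return num / den

        expected = np.array([ring_mean(lo, lo + 30) for lo in
                             np.arange(0, 240, 30.0)])
        expected /= expected[-1]
        assert np.all(np.abs(prof.normalized / expected - 1) <= 0.05)

    def test_reference_ring_outside_field_raises(self, config):
        _, dfield, _ = _disk_field(shape=(128, 128), radius=20.0)
        with pytest.raises(EmptyRingError):
            dm.persistence_profile(np.ones((128, 128)), dfield, config)


def _unit_detections(positions):
    return [BeadDetection(position_um=tuple(p), frame=0, mass=1.0, peak=1.0)
            for p in positions]


class TestShellDensity3D:
    def test_shell_volume_closed_form(self):
        assert dm.ShellDensityProfile.shell_volume_um3(1.0, 2.0) == \
            pytest.approx(4 / 3 * np.pi * 7)
        with pytest.raises(ParameterError):
            dm.ShellDensityProfile.shell_volume_um3(2.0, 1.0)

    def test_no_beads_all_zero(self, config):
        prof = dm.shell_density_3d([], (50, 50, 50), r=10.0, config=config)
        assert np.all(prof.densities == 0.0)

    def test_uniform_field_constant_density(self, uniform_zstack_10k,
                                            config):
        """10^4 unit-intensity beads uniformly outside the spheroid: shell
        densities constant within 10% CV and no radial trend (Poisson-
        weighted slope within 2 s.e. of 0)."""
        params, stack, truth = uniform_zstack_10k
        dets = _unit_detections(truth.bead_positions_um)
        r0 = truth.spheroid_radius_um + params.edge_clearance
        prof = dm.shell_density_3d(
            dets, truth.spheroid_center_um, r=r0,
            config=config, image_shape=stack.channel("bead").shape,
            z_step=params.z_step,
        )
        cv = prof.densities.std() / prof.densities.mean()
        assert cv <= 0.10
        assert abs(poisson_weighted_slope_t(prof)) < 2.0

    def test_centroid_outside_image_rejected(self, config):
        with pytest.raises(ParameterError):
            dm.shell_density_3d([], (500.0, 50.0, 50.0), r=10.0,
                                config=config, image_shape=(10, 64, 64),
                                z_step=5.0)


class TestDensity3DFoldChange:
    def _uniform_profile(self, scale=1.0, n=50):
        rng = np.random.default_rng(0)
        edges = 50.0 + 10.0 * np.arange(7)
        dens = np.full(6, 0.5 * scale)
        return dm.ShellDensityProfile(
            shell_edges_um=edges, densities=dens,
            n_beads=np.full(6, n), r_um=50.0,
        )

    def test_identical_profiles_give_unity(self, config):
        fc = dm.density3d_fold_change(self._uniform_profile(),
                                      self._uniform_profile(), config)
        assert fc.value == 1.0

    def test_doubled_bead_count_doubles_density(self, config):
        """Twice the beads (equal unit intensities) in the target shell
        doubles the measured fold change, within sampling error."""
        rng = np.random.default_rng(9)
        centroid = (100.0, 150.0, 150.0)

        def sample_shell(n, lo, hi):
            u = rng.normal(size=(n, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            radii = (rng.uniform(lo**3, hi**3, n)) ** (1 / 3)
            return centroid + radii[:, None] * u

        shells = [(50, 60), (70, 80), (90, 100)]
        pos0 = np.vstack([sample_shell(300, lo, hi) for lo, hi in shells])
        pos6 = np.vstack([
            sample_shell(600 if lo == 70 else 300, lo, hi)
            for lo, hi in shells
        ])
        prof0 = dm.shell_density_3d(_unit_detections(pos0), centroid,
                                    r=50.0, config=config)
        prof6 = dm.shell_density_3d(_unit_detections(pos6), centroid,
                                    r=50.0, config=config)
        fc = dm.density3d_fold_change(prof0, prof6, config)
        assert fc.value == pytest.approx(2.0, rel=0.05)

    def test_empty_target_shell_raises(self, config):
        p0 = self._uniform_profile()
        p6 = self._uniform_profile()
        p6.n_beads = np.zeros(6, dtype=int)
        with pytest.raises(EmptyRingError):
            dm.density3d_fold_change(p0, p6, config)

    def test_densified_scene_recovers_truth_ratio(self, densification_scene,
                                                  config):
        scene = densification_scene
        fc = dm.density3d_fold_change(scene["profile_t0"],
                                      scene["profile_t6"], config)
        prof0 = scene["profile_t0"]
        i = prof0.shell_index_for_edge_distance(config.shell_offset_3d)
        r_true = scene["truth_t0"].spheroid_radius_um
        lo = max(prof0.shell_edges_um[i] - r_true, 0.0)
        hi = prof0.shell_edges_um[i + 1] - r_true
        gt = scene["truth_t6"].expected_shell_density_factor(lo, hi) \
            / scene["truth_t0"].expected_shell_density_factor(lo, hi)
        assert fc.value == pytest.approx(gt, rel=0.15)


class TestReferenceGroupNormalization:
    def test_reference_normalized_by_itself_has_unit_mean(self):
        vals = [0.8, 1.4, 2.0, 1.2]
        out = dm.normalize_to_reference_group(vals, vals)
        assert np.mean(out) == pytest.approx(1.0)

    def test_worked_example(self):
        assert dm.normalize_to_reference_group([2.0, 4.0], [1.0, 3.0]) == \
            [1.0, 2.0]

    def test_reference_order_irrelevant(self):
        a = dm.normalize_to_reference_group([2.0, 4.0], [1.0, 2.0, 3.0])
        b = dm.normalize_to_reference_group([2.0, 4.0], [3.0, 1.0, 2.0])
        assert a == b

    def test_empty_or_zero_reference_rejected(self):
        with pytest.raises(ParameterError):
            dm.normalize_to_reference_group([1.0], [])
        with pytest.raises(ParameterError):
            dm.normalize_to_reference_group([1.0], [1.0, -1.0])
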