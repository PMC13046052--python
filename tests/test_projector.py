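"""Forward projector and physics augmentations.

The ray tracer is checked against closed forms (slab integrals, linearity,
shift equivariance) and against an independent dense-sampling oracle; each
physics stage is checked against its identity limit and its closed form on
degenerate fields.
"""

import numpy as np
import pytest
from scipy import ndimage

from oracles import dense_ray_integral
from tomosynth.geometry import AcquisitionGeometry
from tomosynth.phantom import PhantomSpec, make_phantom
from tomosynth.projector import (DensityVolume, PhysicsConfig,
                                 apply_beam_hardening, apply_motion_blur,
                                 apply_poisson_noise, apply_scatter,
                                 forward_project, hu_to_density,
                                 load_projections, save_projections,
                                 simulate_projections)
from tomosynth.volumes import HUVolume


def smooth_random_density(seed, n=16, h=3.0, offset_z=150.0):
    """Spatially correlated random density field (smoothed uniform noise).

    Correlated fields are what HU-derived density maps look like; they also
    keep the dense-sampling oracle's own Riemann error well below the
    comparison band (white noise would saturate it at grazing rays).
    """
    rng = np.random.default_rng(seed)
    vals = ndimage.gaussian_filter(rng.uniform(0, 1, (n, n, n)), 1.2, mode="nearest")
    origin = -(n - 1) / 2 * h * np.ones(3)
    origin[2] += offset_z
    return DensityVolume(vals, h, origin)


class TestHuToDensity:
    @pytest.mark.parametrize("hu,rho", [(-1000.0, 0.0), (0.0, 1.0), (-500.0, 0.5),
                                        (300.0, 1.10), (1000.0, 1.55)])
    def test_anchor_table_interpolation(self, hu, rho):
        vol = HUVolume(np.full((2, 2, 2), hu), 1.0)
        assert hu_to_density(vol).values[0, 0, 0] == pytest.approx(rho, abs=1e-12)

    def test_clamped_outside_anchor_range(self):
        vol = HUVolume(np.full((1, 1, 1), 3000.0), 1.0)
        assert hu_to_density(vol).values[0, 0, 0] == 1.55

    def test_rejects_non_monotone_anchors(self):
        vol = HUVolume(np.zeros((1, 1, 1)), 1.0)
        with pytest.raises(ValueError):
            hu_to_density(vol, anchors=((0.0, 1.0), (0.0, 1.1)))


class TestForwardProject:
    def test_zero_volume_projects_to_zero(self, small_geometry):
        dvol = DensityVolume(np.zeros((8, 8, 8)), 3.0, (-10.5, -10.5, 140.0))
        img = forward_project(dvol, small_geometry, 0)
        assert np.all(img == 0)

    def test_uniform_cube_central_ray_slab_integral(self, small_geometry):
        """theta=0 central ray through a uniform cube: mu * depth, 1e-6."""
        n, h = 16, 3.0
        origin = -(n - 1) / 2 * h * np.ones(3)
        origin[2] += 150.0
        dvol = DensityVolume(np.ones((n, n, n)), h, origin)
        img = forward_project(dvol, small_geometry, 4, mu_per_mm=0.02)  # middle view
        center = (small_geometry.detector_shape[0] - 1) // 2
        assert img[center, center] == pytest.approx(0.02 * n * h, abs=1e-6)

    def test_matches_dense_sampling_oracle_all_views(self, small_geometry):
        """Every detector pixel within 0.5% relative (1e-4 absolute for
        near-zero integrals) of 1/20-voxel dense sampling, across the full
        sweep."""
        dvol = smooth_random_density(3)
        for view in range(small_geometry.n_views):
            got = forward_project(dvol, small_geometry, view, mu_per_mm=1.0)
            want = dense_ray_integral(dvol, small_geometry, view)
            near_zero = want <= 1e-4
            assert np.all(np.abs(got[near_zero] - want[near_zero]) <= 1e-4)
            rel = np.abs(got[~near_zero] - want[~near_zero]) / want[~near_zero]
            assert rel.max() < 0.005

    def test_linearity_in_density(self, small_geometry):
        dvol = smooth_random_density(4)
        scaled = DensityVolume(2.5 * dvol.values, dvol.voxel_size_mm, dvol.origin_mm)
        a = forward_project(dvol, small_geometry, 2)
        b = forward_project(scaled, small_geometry, 2)
        assert np.allclose(b, 2.5 * a, rtol=1e-12)

    def test_lateral_shift_equivariance_of_thin_slab(self):
        """Translating an impulse slab laterally by k voxels shifts the
        theta=0 projection by k * M(z) * voxel / pitch pixels."""
        geom = AcquisitionGeometry(sdd_mm=1800.0, n_views=3,
                                   detector_shape=(65, 65), detector_pitch_mm=1.5,
                                   patient_offset_mm=150.0, strip_width_px=5)
        n, h = 16, 3.0
        z_slab = 150.0          # mid-patient depth
        M = geom.magnification(z_slab)
        shift_vox = 2
        imgs = []
        for k in (0, shift_vox):
            vals = np.zeros((n, n, n))
            vals[n // 2 + k, :, n // 2] = 1.0     # slab at depth z ~ 150
            origin = -(n - 1) / 2 * h * np.ones(3)
            origin[2] += z_slab
            dvol = DensityVolume(vals, h, origin)
            imgs.append(forward_project(dvol, geom, 1))
        shift_px = shift_vox * h * M / geom.detector_pitch_mm
        cols = np.arange(imgs[0].shape[1])

        def centroid(img):
            w = img.sum(axis=0)
            return (cols * w).sum() / w.sum()

        measured = centroid(imgs[1]) - centroid(imgs[0])
        assert measured == pytest.approx(shift_px, abs=0.2)

    def test_source_inside_volume_rejected(self, small_geometry):
        dvol = DensityVolume(np.ones((4, 4, 4)), 3.0, (0.0, 0.0, 1795.0))
        with pytest.raises(ValueError):
            forward_project(dvol, small_geometry, 0)


class TestBeamHardening:
    def test_zero_beta_is_identity(self, rng):
        p = rng.uniform(0, 3, (16, 16))
        assert np.array_equal(apply_beam_hardening(p, 0.0), p)

    def test_quadratic_form_point_value(self):
        assert apply_beam_hardening(np.array([1.0]), 0.1)[0] == pytest.approx(0.9)

    def test_monotone_over_valid_domain(self):
        p = np.linspace(0, 4.9, 2000)
        out = apply_beam_hardening(p, 0.1)
        assert np.all(np.diff(out) > 0)

    def test_guard_names_attained_max(self):
        with pytest.raises(ValueError, match="6.0"):
            apply_beam_hardening(np.array([6.0]), 0.1)


class TestScatter:
    def test_zero_spr_is_identity(self, rng):
        p = rng.uniform(0, 3, (16, 16))
        assert np.array_equal(apply_scatter(p, 0.0, 5.0), p)

    def test_uniform_field_closed_form(self):
        p = np.full((64, 64), 1.7)
        out = apply_scatter(p, 0.25, 6.0)
        assert np.allclose(out, 1.7 - np.log(1.25), atol=1e-6)

    def test_scatter_only_reduces_line_integrals(self, rng):
        p = rng.uniform(0, 3, (32, 32))
        assert np.all(apply_scatter(p, 0.3, 4.0) <= p + 1e-12)


class TestMotionBlur:
    def test_zero_sd_is_identity(self, rng):
        p = rng.uniform(0, 2, (4, 16, 16))
        assert np.array_equal(apply_motion_blur(p, 0.0, 1, 1.0), p)

    def test_seeded_reproducibility(self, rng):
        p = rng.uniform(0, 2, (4, 16, 16))
        a = apply_motion_blur(p, 0.7, 9, 1.0)
        b = apply_motion_blur(p, 0.7, 9, 1.0)
        assert np.array_equal(a, b)

    def test_interior_column_mass_preserved(self, rng):
        """Linear interpolation conserves column sums away from edges."""
        p = np.zeros((2, 64, 8))
        p[:, 20:44] = rng.uniform(1, 2, (2, 24, 8))
        out = apply_motion_blur(p, 0.4, 3, 1.0)
        assert np.allclose(out.sum(axis=1), p.sum(axis=1), rtol=1e-6)


class TestPoissonNoise:
    def test_huge_photon_count_is_near_identity(self, rng):
        p = rng.uniform(0, 5, (100, 100))
        out = apply_poisson_noise(p, 1e9, 0)
        assert (out - p).std() < 1e-3

    def test_mean_recovery_within_three_standard_errors(self):
        p = np.full((100, 100), 2.0)
        out = apply_poisson_noise(p, 1e4, 7)
        lam = 1e4 * np.exp(-2.0)
        se = 1.0 / np.sqrt(lam * p.size)    # delta method: SD(p') ~ 1/sqrt(lam)
        assert abs(out.mean() - 2.0) < 3 * se

    def test_finite_even_with_zero_counts(self):
        p = np.full((50, 50), 15.0)         # lambda ~ 3e-3: zeros certain
        out = apply_poisson_noise(p, 1e4, 1)
        assert np.all(np.isfinite(out))


@pytest.fixture(scope="module")
def phantom_vol():
    spec = PhantomSpec(grid_shape=(32, 32, 32), voxel_size_mm=3.0, seed=3,
                       body_halfaxes_mm=(42.0, 44.0, 38.0),
                       lung_halfaxes_mm=(14.0, 26.0, 20.0),
                       lung_offsets_mm=((-19.0, 2.0, 3.0), (19.0, 2.0, 3.0)),
                       spine_radius_mm=6.0, n_ribs=3)
    return make_phantom(spec)[0]


class TestSimulatePipeline:
    def test_all_physics_off_reduces_to_line_integrals(self, phantom_vol, small_geometry):
        ideal = simulate_projections(phantom_vol, small_geometry, PhysicsConfig.ideal())
        dvol = hu_to_density(phantom_vol.recentered((0, 0, 150.0)))
        direct = np.stack([forward_project(dvol, small_geometry, v, 0.02)
                           for v in range(small_geometry.n_views)])
        assert np.array_equal(ideal.images, direct)
        assert ideal.augmentations_applied == ("ray_trace",)

    def test_same_seed_bit_identical(self, phantom_vol, small_geometry):
        phys = PhysicsConfig(seed=5)
        a = simulate_projections(phantom_vol, small_geometry, phys)
        b = simulate_projections(phantom_vol, small_geometry, phys)
        assert np.array_equal(a.images, b.images)
        assert a.augmentations_applied == ("ray_trace", "beam_hardening",
                                           "scatter", "motion_blur", "poisson_noise")

    def test_stagewise_closed_form_composition(self, phantom_vol, small_geometry):
        """Mean effect of the full pipeline matches stage-by-stage closed
        forms applied to the noiseless projections (within Monte-Carlo /
        blur-edge error)."""
        phys = PhysicsConfig(beam_hardening_beta=0.03, scatter_spr=0.2,
                             scatter_sigma_px=4.0, motion_sd_mm=0.0,
                             photons_n0=1e5, seed=11)
        noisy = simulate_projections(phantom_vol, small_geometry, phys)
        clean = simulate_projections(phantom_vol, small_geometry,
                                     PhysicsConfig.ideal()).images
        predicted = apply_scatter(apply_beam_hardening(clean, 0.03), 0.2, 4.0)
        resid = noisy.images - predicted
        # Poisson noise is zero-mean on intensities; on log scale the bias is
        # O(1/(2 lambda)); at n0=1e5 and p<~2 that is < 2e-3
        assert abs(resid.mean()) < 5e-3

    def test_tiff_round_trip(self, phantom_vol, small_geometry, tmp_path):
        pset = simulate_projections(phantom_vol, small_geometry, PhysicsConfig(seed=2))
        save_projections(pset, tmp_path / "proj.tif", PhysicsConfig(seed=2))
        back = load_projections(tmp_path / "proj.tif")
        assert np.allclose(back.images, pset.images, atol=1e-5)
        assert back.geometry == pset.geometry
        assert back.augmentations_applied == pset.augmentations_applied
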