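"""Projector geometry, keystone pre-correction and fringe-uniformity error."""

import numpy as np
import pytest

from sfdikit.keystone import (
    ProjectorGeometry,
    SinusoidSpec,
    angle_sweep,
    correct_pattern,
    corrected_projection_error,
    generate_sinusoid,
    image_to_world,
    keystone_error,
    plane_window_for,
    world_to_image,
)


class TestProjectiveMaps:
    def test_round_trip_is_identity(self, rig_geometry, rng):
        pix = rng.uniform([0, 0], [1280, 800], size=(1000, 2))
        back = world_to_image(image_to_world(pix, rig_geometry), rig_geometry)
        assert np.abs(back - pix).max() < 1e-9

    def test_principal_ray_hits_origin_at_zero_tilt(self, rig_geometry):
        g0 = rig_geometry.at_angles(0.0, 0.0)
        pt = image_to_world(np.array([g0.cu, g0.cv]), g0)
        np.testing.assert_allclose(pt, [0.0, 0.0], atol=1e-12)

    def test_height_scales_footprint_linearly(self):
        g1 = ProjectorGeometry(fu=2000, fv=2000, cu=640, cv=400, h=500)
        g2 = ProjectorGeometry(fu=2000, fv=2000, cu=640, cv=400, h=1000)
        p = np.array([100.0, 50.0])
        np.testing.assert_allclose(image_to_world(p, g2), 2 * image_to_world(p, g1))

    def test_zero_tilt_is_pure_perspective_scaling(self, rig_geometry):
        g0 = rig_geometry.at_angles(0.0, 0.0)
        world = np.array([[12.0, -7.0]])
        pix = world_to_image(world, g0)
        assert pix[0, 0] == pytest.approx(g0.cu + g0.fu * 12.0 / g0.h)
        assert pix[0, 1] == pytest.approx(g0.cv + g0.fv * -7.0 / g0.h)

    def test_tilted_map_matches_pinhole_composition_oracle(self, rig_geometry):
        """Independent oracle: K^-1 pixel ray rotated by Rx(a) @ Ry(b),
        intersected with the plane z = -h."""
        a, b = np.deg2rad(20.0), np.deg2rad(0.5)
        rx = np.array(
            [[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]]
        )
        ry = np.array(
            [[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]]
        )
        g = rig_geometry
        pix = np.array([300.0, 150.0])
        ray = rx @ ry @ np.array(
            [(pix[0] - g.cu) / g.fu, (pix[1] - g.cv) / g.fv, -1.0]
        )
        t = -g.h / ray[2]
        np.testing.assert_allclose(image_to_world(pix, g), (t * ray)[:2], rtol=1e-12)

    def test_rig_intrinsics_accepted(self):
        ProjectorGeometry(fu=2116.8, fv=2122.4, cu=670.4, cv=-186.8, h=527.0)

    def test_parallel_ray_rejected(self):
        g = ProjectorGeometry(fu=100, fv=100, cu=0, cv=0, h=100, alpha=89.0)
        with pytest.raises(ValueError):
            # ray tilted past horizontal for large pixel offsets
            image_to_world(np.array([0.0, 40000.0]), g)


class TestSinusoidGeneration:
    def test_maxima_spacing_equals_period(self):
        img = generate_sinusoid(SinusoidSpec(period_px=40, size=(4, 200)))
        row = img[0]
        maxima = [i for i in range(1, 199) if row[i] >= row[i - 1] and row[i] >= row[i + 1]]
        assert np.all(np.diff(maxima) == 40)

    def test_three_phases_are_cyclic_shifts(self):
        base = generate_sinusoid(SinusoidSpec(period_px=30, phase=0.0, size=(2, 90)))
        shifted = generate_sinusoid(
            SinusoidSpec(period_px=30, phase=2 * np.pi / 3, size=(2, 90))
        )
        # +2pi/3 phase advances the pattern by a third of a period leftward
        np.testing.assert_allclose(np.roll(base, -10, axis=1), shifted, atol=1e-12)

    def test_mean_over_integer_periods(self):
        img = generate_sinusoid(SinusoidSpec(period_px=25, size=(3, 100)))
        assert img.mean() == pytest.approx(0.5, abs=1e-12)
        assert img.min() >= 0 and img.max() <= 1


class TestKeystoneError:
    def test_column_constant_image_scores_zero(self):
        img = np.tile(np.linspace(0, 1, 8), (5, 1))
        assert keystone_error(img) == 0.0

    def test_worked_two_column_example(self):
        img = np.array([[0.0, 1.0], [0.0, 0.5], [0.0, 0.0]])
        # columns (0,0,0) and (1,0.5,0): stds 0 and 0.5 -> mean 0.25
        assert keystone_error(img) == pytest.approx(0.25, rel=1e-12)

    def test_affine_intensity_invariance(self, rng):
        img = rng.random((10, 10))
        assert keystone_error(3.0 * img + 11.0) == pytest.approx(
            keystone_error(img), rel=1e-9
        )

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            keystone_error(np.zeros((0, 3)))


class TestCorrection:
    def test_zero_tilt_correction_is_identity(self, rig_geometry):
        g0 = rig_geometry.at_angles(0.0, 0.0)
        spec = SinusoidSpec(period_px=40, size=(50, 80))
        np.testing.assert_allclose(
            correct_pattern(spec, g0), generate_sinusoid(spec), atol=1e-9
        )

    def test_correct_angles_flatten_fringes(self, rig_geometry):
        """Correcting at the true angles yields column-constant fringes; any
        angle error strictly increases ep."""
        spec = SinusoidSpec(period_px=40, size=(200, 320))
        window = plane_window_for(rig_geometry, spec.size)
        ep_true = corrected_projection_error(
            (20.0, 0.5), rig_geometry, spec, window, (100, 100)
        )
        ep_wrong = corrected_projection_error(
            (16.0, 0.0), rig_geometry, spec, window, (100, 100)
        )
        ep_uncorrected = corrected_projection_error(
            (0.0, 0.0), rig_geometry, spec, window, (100, 100)
        )
        assert ep_true < 1e-10
        assert ep_true < ep_wrong < ep_uncorrected


class TestAngleSweep:
    def test_recovers_true_angles_on_subgrid(self, rig_geometry):
        spec = SinusoidSpec(period_px=40, size=(160, 256))
        window = plane_window_for(rig_geometry, spec.size)

        def ep(a, b):
            return corrected_projection_error((a, b), rig_geometry, spec, window, (80, 80))

        best_a, best_b, surface = angle_sweep(
            ep, alphas=np.arange(18.0, 22.5, 1.0), betas=np.arange(0.0, 1.05, 0.25)
        )
        assert (best_a, best_b) == (20.0, 0.5)
        assert surface.min() == surface[2, 2]

    def test_flat_surface_ties_to_first_grid_point(self):
        with pytest.warns(UserWarning, match="tied"):
            a, b, _ = angle_sweep(
                lambda a, b: 1.0, alphas=np.array([12.0, 13.0]), betas=np.array([0.0, 0.1])
            )
        assert (a, b) == (12.0, 0.0)

    def test_single_point_grid(self):
        a, b, surface = angle_sweep(
            lambda a, b: 0.3, alphas=np.array([15.0]), betas=np.array([0.4])
        )
        assert (a, b) == (15.0, 0.4) and surface.shape == (1, 1)
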