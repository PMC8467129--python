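"""Multi-frequency inversion and phantom linear correction."""

import numpy as np
import pytest

from sfdikit.demodulation import ReflectanceImage
from sfdikit.forward_model import MediumConstants, OpticalProperties, diffuse_reflectance
from sfdikit.inversion import (
    MUA_BOUNDS,
    MUSP_BOUNDS,
    ReflectanceSpectrum,
    apply_correction,
    invert_map,
    invert_point,
    linear_correction,
)

FX = np.array([0.0, 0.042, 0.084, 0.14])


def model_spectrum(mua, musp, fx=FX, medium=None):
    props = OpticalProperties(mua, musp)
    rd = np.array([diffuse_reflectance(props, f, medium) for f in fx])
    return ReflectanceSpectrum(fx=fx, rd=rd)


class TestInvertPoint:
    def test_recovers_generating_parameters(self):
        res = invert_point(model_spectrum(0.02, 1.2))
        assert res.converged
        assert res.props.mua == pytest.approx(0.02, rel=1e-3)
        assert res.props.musp == pytest.approx(1.2, rel=1e-3)

    def test_single_repeated_frequency_flagged_not_raised(self):
        spec = ReflectanceSpectrum(fx=np.array([0.1, 0.1]), rd=np.array([0.3, 0.3]))
        res = invert_point(spec)
        assert not res.converged
        assert "ill-posed" in res.message

    def test_beats_grid_search_oracle(self):
        """The optimiser's residual is <= the best residual on a 200 x 200
        brute-force grid over the fit bounds."""
        spec = model_spectrum(0.08, 0.9)
        res = invert_point(spec)
        muas = np.linspace(MUA_BOUNDS[0], MUA_BOUNDS[1], 200)
        musps = np.linspace(MUSP_BOUNDS[0], MUSP_BOUNDS[1], 200)
        best = np.inf
        for mua in muas:
            props_rd = np.array(
                [
                    [diffuse_reflectance(OpticalProperties(mua, musp), f) for f in spec.fx]
                    for musp in musps
                ]
            )
            best = min(best, float(np.min(np.sum((props_rd - spec.rd) ** 2, axis=1))))
        assert res.residual_norm**2 <= best + 1e-15

    def test_recovery_over_random_draws_noiseless(self, rng):
        """50 random (mua, mus') in bounds recover to <= 0.1% from exact spectra."""
        for _ in range(50):
            mua = rng.uniform(0.005, 0.5)
            musp = rng.uniform(0.3, 3.0)
            res = invert_point(model_spectrum(mua, musp))
            assert abs(res.props.mua - mua) / mua < 1e-3
            assert abs(res.props.musp - musp) / musp < 1e-3

    def test_recovery_with_reflectance_noise(self, rng):
        """1% Gaussian noise on Rd: median parameter error <= 5% relative."""
        errs = []
        for _ in range(50):
            mua = rng.uniform(0.005, 0.5)
            musp = rng.uniform(0.3, 3.0)
            spec = model_spectrum(mua, musp)
            noisy = ReflectanceSpectrum(
                fx=spec.fx, rd=spec.rd * (1 + 0.01 * rng.standard_normal(spec.rd.size))
            )
            res = invert_point(noisy)
            errs.append(
                max(abs(res.props.mua - mua) / mua, abs(res.props.musp - musp) / musp)
            )
        assert np.median(errs) <= 0.05


class TestInvertMap:
    def test_uniform_scene_gives_uniform_maps(self):
        spec = model_spectrum(0.05, 1.0)
        images = [
            ReflectanceImage(rd=np.full((4, 4), rd), fx=fx)
            for fx, rd in zip(spec.fx, spec.rd)
        ]
        mua_map, musp_map = invert_map(images)
        point = invert_point(spec)
        np.testing.assert_allclose(mua_map, point.props.mua, rtol=1e-6)
        np.testing.assert_allclose(musp_map, point.props.musp, rtol=1e-6)

    def test_two_region_scene_recovers_both_truths(self):
        bg, lesion = (0.02, 1.2), (0.04, 0.9)
        mask = np.zeros((6, 6), dtype=bool)
        mask[2:4, 2:4] = True
        images = []
        for fx in FX:
            rd = np.where(
                mask,
                diffuse_reflectance(OpticalProperties(*lesion), fx),
                diffuse_reflectance(OpticalProperties(*bg), fx),
            )
            images.append(ReflectanceImage(rd=rd, fx=fx))
        mua_map, musp_map = invert_map(images)
        assert np.nanmean(mua_map[mask]) == pytest.approx(lesion[0], rel=1e-3)
        assert np.nanmean(musp_map[~mask]) == pytest.approx(bg[1], rel=1e-3)

    def test_masked_pixels_propagate(self):
        images = [
            ReflectanceImage(rd=np.full((2, 2), np.nan), fx=fx) for fx in FX
        ]
        mua_map, musp_map = invert_map(images)
        assert np.all(np.isnan(mua_map)) and np.all(np.isnan(musp_map))

    def test_shape_mismatch_rejected(self):
        images = [
            ReflectanceImage(rd=np.zeros((2, 2)), fx=0.0),
            ReflectanceImage(rd=np.zeros((3, 3)), fx=0.1),
        ]
        with pytest.raises(ValueError, match="co-registered"):
            invert_map(images)


class TestLinearCorrection:
    @pytest.mark.parametrize(
        "ref, mea, expected",
        [
            ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 1.0),
            ([2.0, 4.0], [1.0, 2.0], 2.0),
            ([1.0, 2.0], [2.0, 2.0], 0.75),
        ],
    )
    def test_ratio_values(self, ref, mea, expected):
        assert linear_correction(ref, mea) == pytest.approx(expected, rel=1e-12)

    def test_zero_measurement_rejected(self):
        with pytest.raises(ValueError):
            linear_correction([1.0], [0.0])

    def test_corrects_known_multiplicative_bias(self, rng):
        """A system bias b is removed exactly: calibrated/reference -> 1."""
        ref = rng.uniform(0.1, 2.0, 9)
        b = 1.17
        measured = ref * b
        k = linear_correction(ref, measured)
        calibrated = apply_correction(measured, k)
        np.testing.assert_allclose(calibrated / ref, 1.0, rtol=1e-12)
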