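"""Field-comparison metrics: RMSDn, RMSD, FWHM, EMD, COTM, curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_emd, random_sparse_pattern
from fusim.grids import ComplexPressureVolume, TemperatureSeries
from fusim.metrics import (center_of_thermal_mass, delta_cotm, emd, fwhm,
                           peak_difference, resample_field, rmsd_temperature,
                           rmsdn_pressure, temperature_curves)


def _vol(values, vs=0.25):
    return ComplexPressureVolume(np.asarray(values, complex), vs, (0, 0, 0),
                                 940e3)


class TestResampleField:
    def test_identity_for_equal_spacing(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(size=(6, 7, 8))
        assert np.array_equal(resample_field(f, 0.25, 0.25), f)

    def test_constant_preserved(self):
        f = np.full((8, 8, 8), 3.3)
        out = resample_field(f, 0.25, 0.4)
        assert np.allclose(out, 3.3, rtol=1e-12)

    def test_affine_field_reproduced_exactly(self):
        # trilinear interpolation is exact on affine functions
        i, j, k = np.meshgrid(*[np.arange(12)] * 3, indexing="ij")
        f = 2.0 * i - 0.5 * j + 0.25 * k + 1.0
        out = resample_field(f, 1.0, 0.4)
        ii, jj, kk = np.meshgrid(
            *[np.arange(s) * 0.4 for s in out.shape], indexing="ij")
        assert np.allclose(out, 2.0 * ii - 0.5 * jj + 0.25 * kk + 1.0,
                           atol=1e-10)


class TestRmsdnPressure:
    def test_identical_patterns_give_zero(self):
        rng = np.random.default_rng(3)
        v = _vol(rng.uniform(size=(45, 45, 45)))
        assert rmsdn_pressure(v, v, (22, 22, 22), 20) == 0.0

    def test_constant_offset_closed_form(self):
        exp = _vol(np.ones((41, 41, 41)))
        sim = _vol(1.1 * np.ones((41, 41, 41)))
        assert rmsdn_pressure(sim, exp, (20, 20, 20), 20) \
            == pytest.approx(10.0, rel=1e-9)

    def test_single_delta_closed_form(self):
        exp_arr = np.zeros((41, 41, 41))
        exp_arr[20, 20, 20] = 2.5      # the global max
        sim = _vol(np.zeros((41, 41, 41)))
        val = rmsdn_pressure(sim, _vol(exp_arr), (20, 20, 20), 20)
        assert val == pytest.approx(100.0 / np.sqrt(41**3), rel=1e-9)
        assert val == pytest.approx(0.3809, abs=5e-4)

    def test_zero_reference_rejected(self):
        z = _vol(np.zeros((41, 41, 41)))
        with pytest.raises(ValueError, match="normalizer"):
            rmsdn_pressure(z, z, (20, 20, 20), 20)

    def test_region_must_fit(self):
        v = _vol(np.ones((30, 30, 30)))
        with pytest.raises(ValueError, match="region"):
            rmsdn_pressure(v, v, (15, 15, 15), 20)


class TestRmsdTemperature:
    def test_identical_frames(self):
        f = np.random.default_rng(1).uniform(1, 5, size=(10, 10, 10))
        assert rmsd_temperature(f, f) == (0.0, 0.0)

    def test_uniform_offset(self):
        exp = np.full((8, 8, 8), 4.0)
        rmsd, rmsdn = rmsd_temperature(exp + 1.0, exp)
        assert rmsd == pytest.approx(1.0)
        assert rmsdn == pytest.approx(25.0)

    def test_proportional_fields_closed_form(self):
        exp = np.full((8, 8, 8), 10.0)
        rmsd, rmsdn = rmsd_temperature(1.1 * exp, exp)
        assert rmsd == pytest.approx(1.0, rel=1e-9)
        assert rmsdn == pytest.approx(10.0, rel=1e-9)


class TestFwhm:
    def test_isotropic_gaussian(self):
        n, vs = 81, 0.25
        x = (np.arange(n) - n // 2) * vs
        g = np.exp(-(x[:, None, None] ** 2 + x[None, :, None] ** 2
                     + x[None, None, :] ** 2) / 2.0)   # sigma = 1 mm
        w = fwhm(g, vs)
        assert np.allclose(w, 2.3548, atol=vs)

    def test_scale_invariance(self):
        n, vs = 41, 0.5
        x = (np.arange(n) - n // 2) * vs
        g = np.exp(-(x[:, None, None] ** 2 + x[None, :, None] ** 2
                     + x[None, None, :] ** 2) / 3.0)
        assert np.array_equal(fwhm(g, vs), fwhm(123.4 * g, vs))

    def test_single_voxel_impulse_degenerate(self):
        f = np.zeros((9, 9, 9))
        f[4, 4, 4] = 1.0
        with pytest.warns(UserWarning, match="unresolved"):
            w = fwhm(f, 0.5)
        assert np.allclose(w, 0.5)

    def test_unbounded_lobe_rejected(self):
        f = np.ones((9, 9, 9))
        f[4, 4, 4] = 1.1
        with pytest.raises(ValueError, match="unbounded"):
            fwhm(f, 0.5)


class TestPeakDifference:
    def test_equal_peaks(self):
        f = np.random.default_rng(0).uniform(size=(5, 5, 5))
        assert peak_difference(f, f.copy()) == 0.0

    def test_nine_percent_case(self):
        assert peak_difference(np.array([1.09]), np.array([1.0])) \
            == pytest.approx(9.0)

    def test_asymmetry_documented(self):
        a, b = np.array([1.0]), np.array([2.0])
        assert peak_difference(a, b) == pytest.approx(50.0)
        assert peak_difference(b, a) == pytest.approx(100.0)


class TestEmd:
    def test_identical_patterns(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=(8, 8))
        assert emd(p, p) == pytest.approx(0.0, abs=1e-9)

    def test_point_shift(self):
        a = np.zeros((8, 8))
        b = np.zeros((8, 8))
        a[1, 1] = 2.0
        b[1, 4] = 5.0          # masses are normalized away
        assert emd(a, b) == pytest.approx(3.0, rel=1e-9)

    def test_two_point_split(self):
        a = np.zeros((6, 6))
        a[0, 0] = 0.5
        a[0, 4] = 0.5
        b = np.zeros((6, 6))
        b[0, 2] = 1.0
        assert emd(a, b) == pytest.approx(2.0, rel=1e-9)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError, match="zero-mass"):
            emd(np.zeros((4, 4)), np.ones((4, 4)))

    def test_matches_brute_force_on_random_patterns(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            a = random_sparse_pattern(rng)
            b = random_sparse_pattern(rng)
            # equalize totals with integer masses for the enumeration
            A, B = a * b.sum(), b * a.sum()
            assert emd(a, b) == pytest.approx(
                brute_force_emd(A, B) / A.sum(), abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        a = random_sparse_pattern(rng)
        b = random_sparse_pattern(rng)
        c = random_sparse_pattern(rng)
        dab, dba = emd(a, b), emd(b, a)
        assert dab == pytest.approx(dba, abs=1e-8)        # symmetry
        assert emd(a, a) == pytest.approx(0.0, abs=1e-9)  # identity
        assert emd(a, c) <= dab + emd(b, c) + 1e-8        # triangle


class TestCotm:
    def test_symmetric_gaussian_centroid(self):
        n, vs = 21, 0.5
        x = (np.arange(n) - n // 2) * vs
        g = 5 * np.exp(-(x[:, None, None] ** 2 + x[None, :, None] ** 2
                         + x[None, None, :] ** 2) / 2.0)
        com = center_of_thermal_mass(g, vs, origin=(-5.0, -5.0, -5.0),
                                     threshold=1.0)
        assert np.allclose(com, 0.0, atol=1e-9)

    def test_two_point_weighted_mean(self):
        f = np.zeros((3, 3, 21))
        f[1, 1, 0] = 2.0
        f[1, 1, 20] = 2.0
        com = center_of_thermal_mass(f, 0.5, threshold=1.0)
        assert com[2] == pytest.approx(5.0)   # halfway along 10 mm

    def test_translation_equivariance(self):
        rng = np.random.default_rng(2)
        f = np.zeros((12, 12, 12))
        f[3:7, 3:7, 3:7] = rng.uniform(1.5, 4.0, size=(4, 4, 4))
        a = center_of_thermal_mass(f, 0.5)
        b = center_of_thermal_mass(np.roll(f, 2, axis=2), 0.5)
        assert np.allclose(b - a, [0, 0, 1.0], atol=1e-12)

    def test_empty_mass_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            center_of_thermal_mass(np.zeros((4, 4, 4)), 0.5, threshold=1.0)

    def test_delta_cotm_is_euclidean(self):
        assert delta_cotm([0, 0, 0], [3.0, 4.0, 0]) == pytest.approx(5.0)


class TestTemperatureCurves:
    def _series(self, fields, times=None, vs=0.5):
        fields = np.asarray(fields, float)
        if times is None:
            times = np.arange(fields.shape[0], dtype=float)
        return TemperatureSeries(times, fields, vs, (0, 0, 0))

    def test_uniform_heating_peak_equals_mean(self):
        frames = np.stack([np.full((11, 11, 11), v)
                           for v in (0.0, 1.0, 2.0)])
        _, peak, mean = temperature_curves(self._series(frames))
        assert np.allclose(peak, mean)
        assert np.allclose(peak, [0, 1, 2])

    @pytest.mark.filterwarnings("ignore:mean-temperature cube clipped")
    def test_linear_rise_slope(self):
        # uniform heating: dT/dt = Q/(rho c_p)
        slope = 1e6 / (1093 * 3316.0)
        times = np.arange(5, dtype=float)
        frames = np.stack([np.full((11, 11, 11), slope * t) for t in times])
        _, peak, _ = temperature_curves(self._series(frames, times))
        assert np.allclose(np.diff(peak), slope, rtol=1e-12)

    def test_cooling_peak_strictly_decreasing(self):
        n = 15
        x = np.arange(n) - n // 2
        g = np.exp(-(x[:, None, None] ** 2 + x[None, :, None] ** 2
                     + x[None, None, :] ** 2) / 6.0)
        frames = np.stack([g * np.exp(-0.3 * t) for t in range(4)])
        _, peak, _ = temperature_curves(self._series(frames))
        assert np.all(np.diff(peak) < 0)

    def test_clipped_cube_warns(self):
        frames = np.zeros((2, 6, 6, 6))
        frames[1, 0, 0, 0] = 5.0
        with pytest.warns(UserWarning, match="clipped"):
            temperature_curves(self._series(frames))
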