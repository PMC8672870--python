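"""Angular spectrum and hybrid angular spectrum propagation."""

import numpy as np
import pytest

from conftest import gaussian_focused_plane
from fusim.grids import ComplexPressurePlane, VoxelModel
from fusim.phantom import uniform_model
from fusim.propagate import (PropagationSettings, angular_spectrum_step,
                             expand_plane_to_volume, has_propagate,
                             reflection_pass)

F0 = 940e3
C_WATER = 1482.0


def _random_plane(n=64, seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    return ComplexPressurePlane(vals, 0.25, 0.0, F0)


class TestAngularSpectrumStep:
    def test_zero_distance_is_identity(self):
        p = _random_plane()
        out = angular_spectrum_step(p, 0.0, C_WATER)
        assert np.allclose(out.values, p.values, atol=1e-14)

    def test_plane_wave_accumulates_exact_phase(self):
        p = ComplexPressurePlane(np.ones((32, 32), complex), 0.25, 0.0, F0)
        d = 7.5
        out = angular_spectrum_step(p, d, C_WATER)
        expected = np.exp(-1j * 2 * np.pi * F0 * d * 1e-3 / C_WATER)
        assert np.allclose(out.values, expected, atol=1e-12)

    def test_forward_backward_round_trip_on_propagating_components(self):
        import scipy.fft as sfft
        p = _random_plane()
        fwd = angular_spectrum_step(p, 5.0, C_WATER, evanescent_mode="zero")
        back = angular_spectrum_step(fwd, -5.0, C_WATER,
                                     evanescent_mode="zero")
        k = 2 * np.pi * F0 / C_WATER
        kx = 2 * np.pi * sfft.fftfreq(64, d=0.25e-3)
        mask = kx[:, None] ** 2 + kx[None, :] ** 2 <= k**2
        spec = sfft.fft2(p.values)
        spec[~mask] = 0
        projected = sfft.ifft2(spec)
        assert np.abs(back.values - projected).max() \
            <= 1e-10 * np.abs(projected).max()

    def test_rejects_non_finite_field(self):
        vals = np.ones((16, 16), complex)
        p = ComplexPressurePlane(vals, 0.25, 0.0, F0)
        p.values[3, 3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            angular_spectrum_step(p, 1.0, C_WATER)


class TestExpandPlaneToVolume:
    def test_single_plane_at_source_z_is_input(self, no_pad):
        p = _random_plane()
        vol = expand_plane_to_volume(p, [0.0], C_WATER, settings=no_pad)
        assert np.allclose(vol.values[:, :, 0], p.values, atol=1e-13)

    def test_lossy_plane_wave_beer_lambert(self, no_pad):
        alpha = 3.0  # Np/m
        p = ComplexPressurePlane(np.ones((32, 32), complex), 0.25, 0.0, F0)
        vol = expand_plane_to_volume(p, [0.0, 10.0, 20.0], C_WATER, alpha,
                                     settings=no_pad)
        on_axis = np.abs(vol.values[16, 16, :])
        assert on_axis == pytest.approx(np.exp(-alpha * np.array(
            [0.0, 0.010, 0.020])), rel=1e-9)

    def test_gaussian_beam_width_evolution(self, no_pad):
        # paraxial Gaussian beam: w(z)² = w0²(1 + (z/zR)²)
        n, vs = 128, 0.25
        w0 = 3.0e-3
        lam = C_WATER / F0
        zR = np.pi * w0**2 / lam
        x = (np.arange(n) - (n - 1) / 2) * vs * 1e-3
        r2 = x[:, None] ** 2 + x[None, :] ** 2
        p = ComplexPressurePlane(np.exp(-r2 / w0**2) + 0j, vs, 0.0, F0)
        z = 0.5 * zR * 1e3  # mm
        vol = expand_plane_to_volume(p, [z], C_WATER, settings=no_pad)
        prof = np.abs(vol.values[:, n // 2, 0])
        # second moment of |p|² for the field exp(-r²/w²) gives <x²> = w²/4
        w_meas = 2 * np.sqrt(np.sum(prof**2 * x**2) / np.sum(prof**2))
        w_expect = w0 * np.sqrt(1 + (0.5) ** 2)
        assert w_meas == pytest.approx(w_expect, rel=0.01)


class TestHasPropagate:
    def test_homogeneous_model_reduces_to_angular_spectrum(self, water_model):
        model = water_model((48, 48, 40))
        src = gaussian_focused_plane(model, 4.0, 8.0)
        settings = PropagationSettings(reflection_passes=0)
        has = has_propagate(model, src, settings)
        z = has.origin[2] + np.arange(40) * model.voxel_size
        ref = expand_plane_to_volume(src, z, C_WATER, settings=settings)
        err = np.abs(has.values - ref.values).max()
        assert err <= 1e-9 * np.abs(ref.values).max()

    def test_gelatin_slab_beer_lambert(self, no_pad):
        model = uniform_model("gelatin_70", (32, 32, 120), 0.25)
        src = ComplexPressurePlane(np.ones((32, 32), complex), 0.25,
                                   model.origin[2] - 0.125, F0)
        vol = has_propagate(model, src, no_pad)
        transmitted = np.abs(vol.values[16, 16, -1])
        assert transmitted == pytest.approx(np.exp(-5.264 * 0.030), abs=1e-6)

    def test_linearity_in_source(self, water_model, no_pad):
        model = water_model((32, 32, 20))
        src = gaussian_focused_plane(model, 3.0, 5.0)
        scaled = ComplexPressurePlane(3.7 * src.values, src.pixel_size,
                                      src.plane_z, src.frequency)
        a = has_propagate(model, src, no_pad)
        b = has_propagate(model, scaled, no_pad)
        assert np.allclose(b.values, 3.7 * a.values, rtol=1e-13)

    def test_power_conserved_in_lossless_homogeneous_model(self, water_model):
        model = water_model((96, 96, 40))
        src = gaussian_focused_plane(model, 4.0, 20.0)
        settings = PropagationSettings(evanescent_mode="zero",
                                       reflection_passes=0)
        vol = has_propagate(model, src, settings)
        power = np.sum(np.abs(vol.values) ** 2, axis=(0, 1))
        assert power.max() / power.min() - 1 < 1e-3

    def test_frequency_mismatch_rejected(self, water_model, no_pad):
        model = water_model((16, 16, 8))
        src = ComplexPressurePlane(np.ones((16, 16), complex),
                                   model.voxel_size,
                                   model.origin[2] - model.voxel_size / 2,
                                   1.1e6)
        with pytest.raises(ValueError, match="frequency"):
            has_propagate(model, src, no_pad)

    def test_grid_refinement_consistency(self, no_pad):
        # same physical mini-phantom at 0.5 mm and 0.25 mm: focal |p|
        # within 2%
        def run(vs):
            nx, nz = int(12 / vs), int(24 / vs)
            shape = (nx, nx, nz)
            origin = (-(nx - 1) / 2 * vs, -(nx - 1) / 2 * vs, vs / 2)
            model = uniform_model("gelatin_70", shape, vs, origin=origin)
            # oil sphere radius 3 mm at depth 8 mm, on axis
            x = origin[0] + np.arange(nx) * vs
            z = (np.arange(nz) + 0.5) * vs
            inside = (x[:, None, None] ** 2 + x[None, :, None] ** 2
                      + (z[None, None, :] - 8.0) ** 2) <= 9.0
            model.speed[inside] = 1462.0
            model.density[inside] = 940.0
            model.attenuation[inside] = 0.752
            src = gaussian_focused_plane(model, 4.0, 16.0, taper=4)
            vol = has_propagate(model, src,
                                PropagationSettings(reflection_passes=0,
                                                    edge_taper_width=0))
            iz = int(round(16.0 / vs)) - 1
            return np.abs(vol.values[nx // 2, nx // 2, iz])
        coarse, fine = run(0.25), run(0.125)
        assert abs(fine - coarse) / fine < 0.02


class TestReflectionPass:
    def _interface_model(self, lossless=True):
        speed = np.full((16, 16, 80), 1578.5)
        dens = np.full((16, 16, 80), 1093.0)
        speed[:, :, 40:] = 1462.0
        dens[:, :, 40:] = 940.0
        att = np.zeros_like(speed)
        return VoxelModel(speed, att, dens, 0.25, (0, 0, 0.125), F0)

    def test_uniform_impedance_gives_zero_correction(self, water_model,
                                                     no_pad):
        model = water_model((16, 16, 40))
        src = ComplexPressurePlane(np.ones((16, 16), complex), 0.25,
                                   model.origin[2] - 0.125, F0)
        fwd = has_propagate(model, src, no_pad)
        settings = PropagationSettings(pad_fraction=0.0, edge_taper_width=0,
                                       reflection_passes=2)
        total = reflection_pass(model, fwd, settings)
        assert np.array_equal(total.values, fwd.values)

    def test_planar_interface_fresnel_amplitude(self, no_pad):
        model = self._interface_model()
        src = ComplexPressurePlane(np.ones((16, 16), complex), 0.25,
                                   (0, 0, 0.125)[2] - 0.125, F0)
        fwd = has_propagate(model, src, no_pad)
        settings = PropagationSettings(pad_fraction=0.0, edge_taper_width=0,
                                       reflection_passes=1)
        total = reflection_pass(model, fwd, settings)
        reflected = np.abs((total.values - fwd.values)[8, 8, 10])
        z1, z2 = 1093 * 1578.5, 940 * 1462.0
        assert reflected == pytest.approx(abs(z2 - z1) / (z2 + z1),
                                          rel=1e-9)

    def test_fresnel_energy_identity(self):
        z1, z2 = 1093 * 1578.5, 940 * 1462.0
        R = (z2 - z1) / (z2 + z1)
        T = 2 * z2 / (z2 + z1)
        assert R**2 + (z1 / z2) * T**2 == pytest.approx(1.0, abs=1e-12)
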