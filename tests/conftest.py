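"""Shared fixtures and independent oracles for the test suite.

The oracle functions here deliberately re-derive quantities through
routes that share no code with the library: closed-form solutions
(O'Neil spherical-cap field, Gaussian FWHM), and exhaustive enumeration
(integer transport plans for the Earth Mover's Distance).
"""

from __future__ import annotations

import numpy as np
import pytest

from fusim.grids import ComplexPressurePlane
from fusim.phantom import uniform_model
from fusim.propagate import PropagationSettings, _taper_window


@pytest.fixture
def no_pad():
    """Propagation settings with all numerical dressing disabled."""
    return PropagationSettings(pad_fraction=0.0, edge_taper_width=0,
                               reflection_passes=0)


@pytest.fixture
def water_model():
    def make(shape=(48, 48, 30), voxel=0.25):
        nx, ny, _ = shape
        origin = (-(nx - 1) / 2 * voxel, -(ny - 1) / 2 * voxel, voxel / 2)
        return uniform_model("water", shape, voxel, origin=origin)
    return make


def gaussian_focused_plane(model, waist_mm, focus_mm, taper=0):
    """Gaussian-apodized converging source plane at a model's front face."""
    nx, ny = model.shape[:2]
    vs = model.voxel_size
    x = model.origin[0] + np.arange(nx) * vs
    y = model.origin[1] + np.arange(ny) * vs
    r2 = x[:, None] ** 2 + y[None, :] ** 2
    c = float(model.speed[nx // 2, ny // 2, 0])
    k = 2 * np.pi * model.frequency / c * 1e-3
    vals = np.exp(-r2 / waist_mm**2) \
        * np.exp(1j * k * (np.sqrt(r2 + focus_mm**2) - focus_mm))
    if taper:
        vals = (vals * _taper_window(nx, taper)[:, None]
                * _taper_window(ny, taper)[None, :])
    return ComplexPressurePlane(vals, vs, model.origin[2] - vs / 2,
                                model.frequency)


# ---------------------------------------------------------------------------
# oracles


def oneil_on_axis(z_mm, radius_of_curvature_mm, aperture_radius_mm,
                  frequency, speed, density, u0=1.0):
    """|p| on the axis of a uniformly vibrating focused spherical cap.

    Closed form: |p(z)| = 2ρcu₀ |sin(k(r_b − z)/2)| / |1 − z/R| with r_b
    the distance from the cap rim to the axial point.
    """
    z = np.asarray(z_mm, dtype=float)
    R, a = radius_of_curvature_mm, aperture_radius_mm
    h = R - np.sqrt(R**2 - a**2)
    rb = np.sqrt(a**2 + (z - h) ** 2)
    k = 2 * np.pi * frequency / speed
    return (2 * density * speed * u0
            * np.abs(np.sin(k * (rb - z) * 1e-3 / 2)) / np.abs(1 - z / R))


def brute_force_emd(a: np.ndarray, b: np.ndarray) -> float:
    """Exact EMD of two equal-total integer-mass patterns by exhaustive
    enumeration of all integer transport plans (contingency tables)."""
    ia = np.argwhere(a > 0)
    ib = np.argwhere(b > 0)
    wa = a[a > 0].astype(int)
    wb = b[b > 0].astype(int)
    assert wa.sum() == wb.sum(), "totals must match"
    cost = np.linalg.norm(ia[:, None, :] - ib[None, :, :], axis=2)
    na, nb = len(wa), len(wb)
    best = [np.inf]
    plan = np.zeros((na, nb))

    def assign_row(i, remaining_cols):
        if i == na:
            best[0] = min(best[0], float((plan * cost).sum()))
            return

        def split(j, rem):
            if j == nb - 1:
                if rem <= remaining_cols[j]:
                    plan[i, j] = rem
                    remaining_cols[j] -= rem
                    assign_row(i + 1, remaining_cols)
                    remaining_cols[j] += rem
                    plan[i, j] = 0
                return
            for v in range(min(rem, remaining_cols[j]) + 1):
                plan[i, j] = v
                remaining_cols[j] -= v
                split(j + 1, rem - v)
                remaining_cols[j] += v
                plan[i, j] = 0

        split(0, int(wa[i]))

    assign_row(0, list(wb))
    return best[0]


def random_sparse_pattern(rng, shape=(6, 6), n_points=3, max_mass=3):
    """Random small integer-mass pattern for EMD oracle comparisons."""
    p = np.zeros(shape)
    for _ in range(n_points):
        p[rng.integers(shape[0]), rng.integers(shape[1])] += \
            rng.integers(1, max_mass + 1)
    return p
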