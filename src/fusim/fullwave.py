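"""Brute-force full-wave steady-state reference solver.

A first-order k-space pseudospectral time-domain solver for the linear
acoustic equations in heterogeneous media,

    ∂u/∂t = −(1/ρ) ∇p,        ∂ρ'_i/∂t = −ρ ∂u_i/∂x_i + s_i,
    p = c² (ρ'_x + ρ'_y + ρ'_z) ,

with spatial derivatives evaluated spectrally on staggered grids
(half-voxel spectral shifts), the k-space time-step correction
κ = sinc(c_ref |k| Δt / 2), a split-field absorbing boundary layer on all
faces, and absorption modeled as a pressure-proportional damping term with
rate γ = 2αc — which reproduces amplitude decay e^{−αz} exactly at the
(single) drive frequency.

The solver is deliberately the *slow, general* route: it marches the wave
equation to steady state from a monochromatic source plane and extracts the
steady-state pressure-magnitude pattern over the final cycles (by exact
quadrature demodulation at the drive frequency, equivalent to the maximum
pressure per voxel for a settled monochromatic field).  It shares no code
with the split-step propagator and serves as its independent cross-check
on heterogeneous models.

The source plane is injected as an additive mass-source term scaled so the
launched forward wave reproduces the requested complex pressure plane
(amplitude and phase) at the injection plane; a wave of equal amplitude is
launched backward into the absorbing layer behind the source.

Internally float32 for speed; accuracy is set by the grid (≥6 points per
wavelength here) rather than the arithmetic precision.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft

from .grids import ComplexPressurePlane, ComplexPressureVolume, VoxelModel

__all__ = ["fullwave_steady_state"]


def _pml_profile(n, left, right, sigma_max, dtype, stagger=0.0):
    """Per-voxel damping rate σ (1/s), quartic ramp over each pad region."""
    sig = np.zeros(n, dtype=np.float64)
    i = np.arange(n) + stagger
    if left > 0:
        d = np.clip((left - 0.5 - i) / left, 0, None)
        sig = np.maximum(sig, sigma_max * d**4)
    if right > 0:
        d = np.clip((i - (n - right - 0.5)) / right, 0, None)
        sig = np.maximum(sig, sigma_max * d**4)
    return sig.astype(dtype)


def _pad_sizes(n, pml):
    total = sfft.next_fast_len(n + 2 * pml)
    left = (total - n) // 2
    return total, left, total - n - left


def fullwave_steady_state(
    model: VoxelModel,
    source: ComplexPressurePlane,
    cfl: float = 0.45,
    pml_width: int = 10,
    ramp_cycles: int = 4,
    settle_cycles: int = 10,
    record_cycles: int = 2,
    pml_sigma_factor: float = 3.0,
    dtype=np.float32,
) -> ComplexPressureVolume:
    """March the full-wave solver to steady state and demodulate |p|, ∠p.

    Returns a complex phasor volume on the same planes as the split-step
    propagator output (plane iz at the back face of model voxel iz), so the
    two solutions can be compared voxel-for-voxel.
    """
    if abs(source.frequency - model.frequency) > 1e-6 * model.frequency:
        raise ValueError("source/model frequency mismatch")
    if source.values.shape != model.shape[:2]:
        raise ValueError("source plane must match model transverse shape")

    nx, ny, nz = model.shape
    dx = model.voxel_size * 1e-3
    f0 = model.frequency
    w0 = 2 * np.pi * f0
    c_ref = float(model.speed.max())
    c_min = float(model.speed.min())

    # padded grid: PML on all faces; along z an extra node carries the
    # source plane just inside the front PML
    NX, lx, rx = _pad_sizes(nx, pml_width)
    NY, ly, ry = _pad_sizes(ny, pml_width)
    NZ, lz, rz = _pad_sizes(nz + 1, pml_width)
    j_src = lz                       # source-plane node
    # model voxel index sampled at each z node (edge-replicated into pads)
    zvox = np.clip(np.arange(NZ) - j_src, 0, nz - 1)

    def embed(vol):
        out = np.empty((NX, NY, NZ), dtype=dtype)
        core = vol[:, :, zvox]
        out[lx:lx + nx, ly:ly + ny, :] = core
        out[:lx] = out[lx]
        out[lx + nx:] = out[lx + nx - 1]
        out[:, :ly] = out[:, ly:ly + 1]
        out[:, ly + ny:] = out[:, ly + ny - 1:ly + ny]
        return out

    c = embed(model.speed)
    rho = embed(model.density)
    alpha = embed(model.attenuation)
    c2 = c * c
    gamma = 2.0 * alpha * c          # damping rate matching e^{−αz} at f0

    # time step: integer number per period, at or below the CFL limit
    n_per_period = int(np.ceil(1.0 / (f0 * cfl * dx / c_ref)))
    dt = 1.0 / (f0 * n_per_period)

    # spectral operators (rfft along z)
    kx = 2 * np.pi * sfft.fftfreq(NX, d=dx).astype(np.float64)
    ky = 2 * np.pi * sfft.fftfreq(NY, d=dx).astype(np.float64)
    kz = 2 * np.pi * sfft.rfftfreq(NZ, d=dx).astype(np.float64)
    K = np.sqrt(kx[:, None, None] ** 2 + ky[None, :, None] ** 2
                + kz[None, None, :] ** 2)
    kappa = np.sinc(c_ref * K * dt / (2 * np.pi)).astype(np.float64)
    dplus = [  # derivative onto the staggered (+½) grid
        (1j * kx * np.exp(1j * kx * dx / 2))[:, None, None] * kappa,
        (1j * ky * np.exp(1j * ky * dx / 2))[None, :, None] * kappa,
        (1j * kz * np.exp(1j * kz * dx / 2))[None, None, :] * kappa,
    ]
    dminus = [  # derivative back onto the regular grid
        (1j * kx * np.exp(-1j * kx * dx / 2))[:, None, None] * kappa,
        (1j * ky * np.exp(-1j * ky * dx / 2))[None, :, None] * kappa,
        (1j * kz * np.exp(-1j * kz * dx / 2))[None, None, :] * kappa,
    ]
    dplus = [op.astype(np.complex64) for op in dplus]
    dminus = [op.astype(np.complex64) for op in dminus]

    # density at staggered points (arithmetic neighbor mean, edge clamp)
    rho_stag = []
    for a in range(3):
        r2 = 0.5 * (rho + np.roll(rho, -1, axis=a))
        idx = [slice(None)] * 3
        idx[a] = -1
        r2[tuple(idx)] = rho[tuple(idx)]
        rho_stag.append(r2)

    sigma_max = pml_sigma_factor * c_ref / dx
    pml_r, pml_s = [], []   # exp(−σ dt/2) at regular / staggered positions
    pads = [(lx, rx, NX), (ly, ry, NY), (lz, rz, NZ)]
    for a, (l, r, n_tot) in enumerate(pads):
        shp = [1, 1, 1]
        shp[a] = n_tot
        pml_r.append(np.exp(-_pml_profile(n_tot, l, r, sigma_max, np.float64)
                            * dt / 2).astype(dtype).reshape(shp))
        pml_s.append(np.exp(-_pml_profile(n_tot, l, r, sigma_max, np.float64,
                                          stagger=0.5)
                            * dt / 2).astype(dtype).reshape(shp))

    # source drive: additive ∂p/∂t term g(t) at the source-plane nodes,
    # g = (2c/dx)·|P0|·cos(ωt + φ) launches a forward wave |P0|e^{jφ−jkz}.
    # A plane mass source emits oblique components with amplitude ∝ 1/cosθ,
    # so the drive spectrum is pre-weighted by cosθ = k_z/k (evanescent
    # components, which the source cannot launch cleanly, are removed).
    c_plane = float(np.mean(model.speed[:, :, 0]))
    k0 = w0 / c_plane
    sx = 2 * np.pi * sfft.fftfreq(nx, d=dx)
    sy = 2 * np.pi * sfft.fftfreq(ny, d=dx)
    sr2 = sx[:, None] ** 2 + sy[None, :] ** 2
    cos_theta = np.sqrt(np.clip(1.0 - sr2 / k0**2, 0.0, None))
    drive = sfft.ifft2(sfft.fft2(source.values) * cos_theta)
    amp = np.abs(drive).astype(dtype)
    phase = np.angle(drive).astype(dtype)
    c_src = c[lx:lx + nx, ly:ly + ny, j_src]
    # cos(ωΔt/2): time-staggering correction — a discretely sampled
    # harmonic rate source in the leapfrog scheme emits 1/cos(ωΔt/2)
    # stronger than its continuum counterpart
    drive_scale = (2.0 * c_src / dx) * amp * dt / (c_src * c_src) \
        * np.cos(w0 * dt / 2)

    travel_s = NZ * dx / c_min
    n_steps = int(np.ceil(travel_s * f0 + ramp_cycles + settle_cycles
                          + record_cycles) * n_per_period)
    n_record = record_cycles * n_per_period
    n_ramp = ramp_cycles * n_per_period

    u = [np.zeros((NX, NY, NZ), dtype=dtype) for _ in range(3)]
    rhp = [np.zeros((NX, NY, NZ), dtype=dtype) for _ in range(3)]
    p = np.zeros((NX, NY, NZ), dtype=dtype)
    damp = np.exp(-gamma * dt).astype(dtype)

    acc_c = np.zeros((nx, ny, nz), dtype=np.float64)
    acc_s = np.zeros((nx, ny, nz), dtype=np.float64)
    core = (slice(lx, lx + nx), slice(ly, ly + ny),
            slice(j_src + 1, j_src + 1 + nz))

    for step in range(n_steps):
        t = step * dt
        spec = sfft.rfftn(p)
        for a in range(3):
            grad = sfft.irfftn(spec * dplus[a], s=p.shape, axes=(0, 1, 2))
            u[a] = pml_s[a] * (pml_s[a] * u[a]
                               - (dt / rho_stag[a]) * grad.astype(dtype))
        for a in range(3):
            div = sfft.irfftn(sfft.rfftn(u[a]) * dminus[a], s=p.shape,
                              axes=(0, 1, 2))
            rhp[a] = pml_r[a] * (pml_r[a] * rhp[a]
                                 - dt * rho * div.astype(dtype))
            rhp[a] *= damp
        ramp = 0.5 * (1 - np.cos(np.pi * (step + 1) / n_ramp)) \
            if step < n_ramp else 1.0
        rhp[2][lx:lx + nx, ly:ly + ny, j_src] += (
            ramp * drive_scale * np.cos(w0 * (t + dt) + phase))
        p = c2 * (rhp[0] + rhp[1] + rhp[2])
        if step >= n_steps - n_record:
            ph = w0 * (step + 1) * dt
            pc = p[core].astype(np.float64)
            acc_c += pc * np.cos(ph)
            acc_s += pc * np.sin(ph)

    a_c = 2.0 * acc_c / n_record
    a_s = 2.0 * acc_s / n_record
    phasor = a_c - 1j * a_s          # p(t) = Re{P e^{jωt}}
    origin = model.origin + np.array([0.0, 0.0, model.voxel_size / 2])
    return ComplexPressureVolume(phasor, model.voxel_size, origin,
                                 model.frequency)
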