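"""Acoustic-to-thermal coupling and explicit Pennes bioheat FDTD solver.

The absorbed acoustic power density is Q = α|p|²/Z (W/m³) with α the
amplitude attenuation in Np/m, |p| the peak phasor pressure in Pa and
Z = ρc the acoustic impedance in Rayl.  Q drives the Pennes bioheat
equation

    ρc_p ∂T/∂t = ∇·(k ∇T) + Q − w (T − T₀),

solved here for the temperature *rise* T (°C above a uniform baseline,
T₀ = 0) with a forward-Euler finite-difference scheme: harmonic-mean face
conductivities at material interfaces, zero-flux (adiabatic, mirror)
boundaries, and an explicit stability bound dt ≤ min ρc_p Δx²/(6k).  The
perfusion coefficient w (W/m³/°C) defaults to zero — tissue-mimicking
phantoms are not perfused — but is carried for completeness.

The flux-conservative update conserves deposited energy exactly under
adiabatic boundaries (up to round-off), which the test suite exploits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .grids import (LabelMap, PowerDepositionVolume, ComplexPressureVolume,
                    TemperatureSeries, VoxelModel)
from .materials import DEFAULT_MATERIALS, MaterialProperties

__all__ = [
    "ThermalModel",
    "SonicationProtocol",
    "power_deposition",
    "resample_power",
    "stability_bound",
    "pennes_fdtd",
    "thermal_model_from_labels",
]

#: cap applied to the stability bound when conductivity is ~0 somewhere
_BOUND_CAP = 1.0e6


@dataclass
class ThermalModel:
    """Thermal property grids on an isotropic lattice."""

    conductivity: np.ndarray              # W/m/°C
    volumetric_heat_capacity: np.ndarray  # J/m³/°C (ρ·c_p)
    voxel_size: float                     # mm
    perfusion: np.ndarray | None = None   # W/m³/°C

    def __post_init__(self) -> None:
        self.conductivity = np.asarray(self.conductivity, dtype=float)
        self.volumetric_heat_capacity = np.asarray(
            self.volumetric_heat_capacity, dtype=float)
        if self.conductivity.shape != self.volumetric_heat_capacity.shape:
            raise ValueError("thermal grids must share shape")
        if self.conductivity.ndim != 3:
            raise ValueError("thermal grids must be 3D")
        if np.any(self.conductivity <= 0) \
                or np.any(self.volumetric_heat_capacity <= 0):
            raise ValueError("conductivity and heat capacity must be > 0")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.perfusion is None:
            self.perfusion = np.zeros_like(self.conductivity)
        else:
            self.perfusion = np.asarray(self.perfusion, dtype=float)
            if self.perfusion.shape != self.conductivity.shape:
                raise ValueError("perfusion grid shape mismatch")
            if np.any(self.perfusion < 0):
                raise ValueError("perfusion must be >= 0")

    @property
    def shape(self):
        return self.conductivity.shape


@dataclass(frozen=True)
class SonicationProtocol:
    """One timed sonication: heat for ``heat_duration`` s, then cool."""

    heat_duration: float = 20.84   # s
    acoustic_power: float = 50.1   # W (bookkeeping; Q carries the field)
    post_cool: float = 0.0         # s
    sample_interval: float = 1.0   # s between stored frames

    def __post_init__(self) -> None:
        if min(self.heat_duration, self.acoustic_power,
               self.post_cool, self.sample_interval) < 0:
            raise ValueError("protocol values must be non-negative")


def thermal_model_from_labels(
    label_map: LabelMap,
    table: Mapping[str, MaterialProperties] = DEFAULT_MATERIALS,
) -> ThermalModel:
    """Build thermal property grids by label lookup.

    Raises if any material present in the map lacks thermal properties —
    every voxel participates in conduction, so acoustic-only materials are
    a configuration error here.
    """
    labels = label_map.labels
    k = np.empty(labels.shape, dtype=float)
    rcp = np.empty(labels.shape, dtype=float)
    for lab in np.unique(labels):
        name = label_map.label_key[int(lab)]
        m = table[name]
        if not m.has_thermal:
            raise ValueError(
                f"material {name!r} has no thermal properties but is present "
                "in the thermal model")
        mask = labels == lab
        k[mask] = m.thermal_conductivity
        rcp[mask] = m.volumetric_heat_capacity
    return ThermalModel(conductivity=k, volumetric_heat_capacity=rcp,
                        voxel_size=label_map.voxel_size)


def power_deposition(pressure: ComplexPressureVolume,
                     model: VoxelModel) -> PowerDepositionVolume:
    """Q = α|p|²/Z per voxel (W/m³)."""
    if pressure.values.shape != model.shape:
        raise ValueError(
            f"pressure grid {pressure.values.shape} does not match model "
            f"grid {model.shape}")
    Q = model.attenuation * np.abs(pressure.values) ** 2 / model.impedance
    return PowerDepositionVolume(Q=Q, voxel_size=pressure.voxel_size,
                                 origin=pressure.origin.copy())


def resample_power(q: PowerDepositionVolume,
                   target_voxel_size: float) -> PowerDepositionVolume:
    """Down-sample Q to a coarser grid by volume-weighted block averaging.

    The target spacing must be an integer multiple of the source spacing
    (e.g. the 0.25 mm acoustic grid onto the 0.5 mm thermal grid); block
    averaging conserves total deposited power over the covered region.
    """
    ratio = target_voxel_size / q.voxel_size
    f = int(round(ratio))
    if abs(ratio - f) > 1e-9 or f < 1:
        raise ValueError(
            "target voxel size must be an integer multiple of the source "
            f"voxel size (got ratio {ratio})")
    if f == 1:
        return PowerDepositionVolume(q.Q.copy(), q.voxel_size,
                                     q.origin.copy())
    nx, ny, nz = (s // f for s in q.Q.shape)
    trimmed = q.Q[:nx * f, :ny * f, :nz * f]
    blocks = trimmed.reshape(nx, f, ny, f, nz, f).mean(axis=(1, 3, 5))
    # origin moves to the center of the first block
    shift = (f - 1) / 2 * q.voxel_size
    return PowerDepositionVolume(blocks, target_voxel_size,
                                 q.origin + shift)


def stability_bound(thermal: ThermalModel,
                    voxel_size: float | None = None) -> float:
    """Largest stable forward-Euler step: min ρc_p Δx² / (6k), in seconds."""
    dx = (voxel_size if voxel_size is not None else thermal.voxel_size) * 1e-3
    bound = float(np.min(
        thermal.volumetric_heat_capacity * dx**2 / (6 * thermal.conductivity)))
    if bound > _BOUND_CAP:
        warnings.warn("stability bound capped (conductivity near zero)",
                      stacklevel=2)
        return _BOUND_CAP
    return bound


def _face_conductivity(k: np.ndarray, axis: int) -> np.ndarray:
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[axis] = slice(None, -1)
    hi[axis] = slice(1, None)
    a, b = k[tuple(lo)], k[tuple(hi)]
    return 2 * a * b / (a + b)


def _laplacian_term(T: np.ndarray, kf: list[np.ndarray], dx: float):
    """∇·(k∇T) with zero-flux boundaries, W/m³."""
    out = np.zeros_like(T)
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        flux = kf[axis] * (T[tuple(hi)] - T[tuple(lo)]) / dx
        out[tuple(lo)] += flux / dx
        out[tuple(hi)] -= flux / dx
    return out


def pennes_fdtd(
    thermal: ThermalModel,
    Q: PowerDepositionVolume,
    protocol: SonicationProtocol,
    dt: float = 0.1,
    initial: np.ndarray | None = None,
) -> TemperatureSeries:
    """Explicit FDTD solve of the Pennes equation for one sonication.

    Q is applied for ``protocol.heat_duration`` seconds, then switched off
    for ``protocol.post_cool`` seconds of free cooling.  Frames (including
    the initial state) are stored every ``protocol.sample_interval``
    seconds.  Refuses time steps above the explicit stability bound.
    """
    if Q.Q.shape != thermal.shape:
        raise ValueError(
            f"Q grid {Q.Q.shape} does not match thermal grid {thermal.shape};"
            " resample first")
    bound = stability_bound(thermal)
    if dt > bound:
        raise ValueError(
            f"dt = {dt} s exceeds the explicit stability bound {bound:.4g} s")
    if protocol.sample_interval < dt:
        raise ValueError("sample_interval must be >= dt")

    dx = thermal.voxel_size * 1e-3
    rcp = thermal.volumetric_heat_capacity
    w = thermal.perfusion
    kf = [_face_conductivity(thermal.conductivity, a) for a in range(3)]

    T = (np.zeros(thermal.shape) if initial is None
         else np.array(initial, dtype=float))
    n_total = int(np.ceil(
        (protocol.heat_duration + protocol.post_cool) / dt - 1e-9))
    every = max(1, int(round(protocol.sample_interval / dt)))

    times = [0.0]
    frames = [T.copy()]
    for step in range(1, n_total + 1):
        # fraction of this step inside the heating window, so the
        # deposited energy is exactly Q · heat_duration
        hw = np.clip((protocol.heat_duration - (step - 1) * dt) / dt, 0.0, 1.0)
        dTdt = (_laplacian_term(T, kf, dx) + hw * Q.Q - w * T) / rcp
        T = T + dt * dTdt
        if step % every == 0 or step == n_total:
            times.append(step * dt)
            frames.append(T.copy())
    return TemperatureSeries(times=np.array(times), fields=np.stack(frames),
                             voxel_size=thermal.voxel_size,
                             origin=Q.origin.copy())
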