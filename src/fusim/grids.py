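"""Gridded field containers shared across the simulation pipeline.

Conventions (fixed repo-wide):

* right-handed coordinates, z is the beam propagation axis;
* the coordinate origin is the center of the transducer face;
* arrays are indexed ``[ix, iy, iz]``; voxel indices are 0-based and
  positions refer to voxel centers;
* lengths in mm, times in s, pressures in Pa, power density in W/m³,
  temperatures (rises) in °C;
* complex pressures are phasors under the e^{+jωt} time convention, with
  forward propagation carrying phase e^{−jkz}; |p| is the peak pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _as_origin(origin) -> np.ndarray:
    o = np.asarray(origin, dtype=float)
    if o.shape != (3,):
        raise ValueError("origin must be a 3-vector (mm)")
    return o


@dataclass
class LabelMap:
    """Integer segmentation of a phantom volume.

    ``label_key`` maps each integer label to a material name; every label
    value present in ``labels`` must appear in the key.
    """

    labels: np.ndarray           # 3D int grid
    voxel_size: float            # mm, isotropic
    origin: np.ndarray           # mm, center of voxel (0,0,0)
    label_key: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or min(self.labels.shape) < 1:
            raise ValueError("labels must be a 3D grid")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        self.origin = _as_origin(self.origin)
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.label_key)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from label_key")


@dataclass
class VoxelModel:
    """Heterogeneous acoustic medium on an isotropic voxel lattice."""

    speed: np.ndarray        # m/s
    attenuation: np.ndarray  # Np/m (amplitude) at `frequency`
    density: np.ndarray      # kg/m³
    voxel_size: float        # mm
    origin: np.ndarray       # mm
    frequency: float         # Hz

    def __post_init__(self) -> None:
        self.speed = np.asarray(self.speed, dtype=float)
        self.attenuation = np.asarray(self.attenuation, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if not (self.speed.shape == self.attenuation.shape == self.density.shape):
            raise ValueError("speed/attenuation/density grids must share shape")
        if self.speed.ndim != 3:
            raise ValueError("model grids must be 3D")
        if np.any(self.speed <= 0) or np.any(self.density <= 0):
            raise ValueError("speed and density must be strictly positive")
        if np.any(self.attenuation < 0):
            raise ValueError("attenuation must be non-negative")
        if self.voxel_size <= 0 or self.frequency <= 0:
            raise ValueError("voxel_size and frequency must be positive")
        self.origin = _as_origin(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.speed.shape

    @property
    def impedance(self) -> np.ndarray:
        """Z = ρc per voxel (Rayl)."""
        return self.density * self.speed

    def z_centers(self) -> np.ndarray:
        """z coordinate (mm) of each voxel-center plane."""
        return self.origin[2] + self.voxel_size * np.arange(self.shape[2])


@dataclass
class ComplexPressurePlane:
    """2D complex pressure phasor field on a transverse plane."""

    values: np.ndarray   # 2D complex, Pa
    pixel_size: float    # mm
    plane_z: float       # mm
    frequency: float     # Hz
    origin_xy: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2:
            raise ValueError("plane values must be 2D")
        if not np.all(np.isfinite(self.values.view(float))):
            raise ValueError("plane contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        self.origin_xy = np.asarray(self.origin_xy, dtype=float)


@dataclass
class ComplexPressureVolume:
    """3D complex steady-state pressure phasor field (Pa)."""

    values: np.ndarray   # 3D complex
    voxel_size: float    # mm
    origin: np.ndarray   # mm
    frequency: float     # Hz

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("volume values must be 3D")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        self.origin = _as_origin(self.origin)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass
class PowerDepositionVolume:
    """Deposited acoustic power density Q (W/m³)."""

    Q: np.ndarray
    voxel_size: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.ndim != 3:
            raise ValueError("Q must be 3D")
        if np.any(self.Q < 0):
            raise ValueError("Q must be non-negative")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        self.origin = _as_origin(self.origin)


@dataclass
class TemperatureSeries:
    """Time-stamped 3D temperature-rise fields (°C above baseline)."""

    times: np.ndarray    # s, strictly increasing
    fields: np.ndarray   # (nt, nx, ny, nz) °C
    voxel_size: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fields = np.asarray(self.fields, dtype=float)
        if self.times.ndim != 1 or self.fields.ndim != 4:
            raise ValueError("times must be 1D and fields (nt, nx, ny, nz)")
        if len(self.times) != self.fields.shape[0]:
            raise ValueError("times and fields length mismatch")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        self.origin = _as_origin(self.origin)

    def frame(self, i: int) -> np.ndarray:
        return self.fields[i]
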