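"""Cross-validation of the split-step propagator against the full-wave solver.

Defines the reduced heterogeneous benchmark used for quantitative
self-validation: a 30 × 30 × 40 mm voxel model at 0.25 mm (a 30-mm
70%-milk gelatin slab in water containing one 8–10 mm canola-oil sphere at
a seeded position), driven by a Gaussian-apodized spherically-converging
source plane focused inside the gelatin beyond the inclusion.  Both the
hybrid angular spectrum propagator and the brute-force full-wave solver
are run from the identical source plane, and the normalized RMS difference
of the two |p| patterns is evaluated over the 41³-voxel focal region with
the full-wave pattern as the reference.
"""

from __future__ import annotations

import numpy as np

from .grids import ComplexPressurePlane, LabelMap
from .metrics import rmsdn_pressure
from .phantom import assign_properties
from .propagate import PropagationSettings, _taper_window, has_propagate
from .fullwave import fullwave_steady_state

__all__ = ["benchmark_model", "benchmark_source", "run_crossvalidation"]

FREQUENCY = 940e3          # Hz
VOXEL_MM = 0.25
SHAPE = (120, 120, 160)    # 30 x 30 x 40 mm
GEL_Z_MM = (5.0, 35.0)     # gelatin slab extent behind the model front face
FOCUS_DEPTH_MM = 28.0      # source-plane-to-focus distance
INCLUSION_DEPTH_MM = 15.0
BEAM_WAIST_MM = 8.0


def focus_voxel(shape, voxel_size: float = VOXEL_MM) -> tuple[int, int, int]:
    """Voxel index of the beam focus on the benchmark grid."""
    return (shape[0] // 2, shape[1] // 2,
            int(round(FOCUS_DEPTH_MM / voxel_size)) - 1)


def benchmark_model(seed: int, voxel_size: float = VOXEL_MM, shape=SHAPE):
    """Seeded gelatin-slab-with-oil-inclusion model for cross-validation.

    The oil sphere has a seeded diameter of 8–10 mm and sits on the beam
    path inside the gelatin (center jittered ±1.5 mm transversely and
    axially around 15 mm depth), so the converging beam must traverse it.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    fx, fy, _ = focus_voxel(shape, voxel_size)
    labels = np.zeros(shape, dtype=np.int16)
    # voxel-center coordinates relative to the model front face
    z = (np.arange(nz) + 0.5) * voxel_size
    gel = (z >= GEL_Z_MM[0]) & (z <= GEL_Z_MM[1])
    labels[:, :, gel] = 1

    radius = rng.uniform(4.0, 5.0)
    x = (np.arange(nx) - (nx - 1) / 2) * voxel_size
    y = (np.arange(ny) - (ny - 1) / 2) * voxel_size
    cx = x[fx] + rng.uniform(-1.5, 1.5)
    cy = y[fy] + rng.uniform(-1.5, 1.5)
    cz = INCLUSION_DEPTH_MM + rng.uniform(-1.5, 1.5)
    inside = ((x[:, None, None] - cx) ** 2 + (y[None, :, None] - cy) ** 2
              + (z[None, None, :] - cz) ** 2) <= radius**2
    labels[inside & (labels == 1)] = 2

    lm = LabelMap(labels=labels, voxel_size=voxel_size,
                  origin=np.array([x[0], y[0], voxel_size / 2]),
                  label_key={0: "water", 1: "gelatin_70", 2: "canola_oil"})
    return assign_properties(lm, frequency=FREQUENCY)


def benchmark_source(model, waist_mm: float = BEAM_WAIST_MM,
                     taper_width: int = 16) -> ComplexPressurePlane:
    """Gaussian-apodized converging source plane at the model front face.

    Amplitude exp(−r²/w²) with a spherical phase converging on the focus
    voxel; a raised-cosine edge roll-off is baked into the plane itself so
    both solvers receive literally the same field.
    """
    nx, ny = model.shape[:2]
    vs = model.voxel_size
    fx, fy, fz = focus_voxel(model.shape, vs)
    x = model.origin[0] + np.arange(nx) * vs
    y = model.origin[1] + np.arange(ny) * vs
    cx, cy = x[fx], y[fy]
    zf = (fz + 1) * vs                      # mm beyond the front face
    r2 = (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2
    c_face = float(model.speed[nx // 2, ny // 2, 0])
    k = 2 * np.pi * model.frequency / c_face * 1e-3   # rad/mm
    vals = np.exp(-r2 / waist_mm**2) \
        * np.exp(1j * k * (np.sqrt(r2 + zf**2) - zf))
    vals = (vals * _taper_window(nx, taper_width)[:, None]
            * _taper_window(ny, taper_width)[None, :])
    front_z = model.origin[2] - vs / 2
    return ComplexPressurePlane(vals, vs, front_z, model.frequency)


def run_crossvalidation(seed: int, shape=SHAPE, voxel_size: float = VOXEL_MM,
                        half_width: int = 20) -> dict:
    """HAS vs full-wave RMSDn (%) on the seeded heterogeneous benchmark."""
    model = benchmark_model(seed, voxel_size, shape)
    source = benchmark_source(model)
    settings = PropagationSettings(edge_taper_width=0)  # taper is in-plane
    has = has_propagate(model, source, settings)
    ref = fullwave_steady_state(model, source)
    focus = focus_voxel(shape, voxel_size)
    value = rmsdn_pressure(has, ref, focus, half_width=half_width)
    return {
        "rmsdn_percent": value,
        "n_region_voxels": (2 * half_width + 1) ** 3,
        "focus_voxel": focus,
        "has_peak": float(np.abs(has.values).max()),
        "fullwave_peak": float(np.abs(ref.values).max()),
    }
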