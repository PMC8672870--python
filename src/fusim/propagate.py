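"""Angular-spectrum and hybrid angular spectrum (HAS) beam propagation.

The plain angular spectrum method advances a monochromatic complex pressure
field between parallel planes by Fourier decomposition into plane waves,
each multiplied by e^{−j k_z d} with k_z = sqrt(k² − k_x² − k_y²).  It is
exact for homogeneous media but cannot represent heterogeneity.

The hybrid angular spectrum method extends it to heterogeneous voxel models
with a split-step scheme marching plane by plane along z.  For each
transverse plane of voxels the propagation over the slab thickness Δz is
split into:

* a **space-domain step**: voxel-wise multiplication by
  e^{−j (k(x,y) − k̄) Δz} · e^{−α(x,y) Δz}, where k(x,y) = 2πf/c(x,y) and
  k̄ is the plane-average wavenumber — this carries the voxel-specific phase
  deviation from the planar average and all attenuation;
* a **spectral step**: a lossless angular-spectrum advance by Δz using the
  planar-averaged wavenumber k̄.

For a homogeneous model the space-domain factor reduces to pure attenuation
and the scheme collapses to the traditional angular spectrum method.
Reflections are handled by optional marching passes that seed reflected
waves at voxel-column impedance steps (normal-incidence Fresnel
coefficients) and re-propagate them with the same split-step scheme, summed
coherently.

Phasor convention: e^{+jωt} time dependence, forward phase e^{−jkz}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft

from .grids import ComplexPressurePlane, ComplexPressureVolume, VoxelModel

__all__ = [
    "PropagationSettings",
    "angular_spectrum_step",
    "expand_plane_to_volume",
    "has_propagate",
    "reflection_pass",
]


@dataclass
class PropagationSettings:
    """Numerical controls for the split-step propagators.

    pad_fraction
        Zero-padding added per transverse side (fraction of grid size)
        before FFTs, cropped on output; suppresses wrap-around.
    evanescent_mode
        "decay": evanescent spectral components decay exponentially
        (imaginary k_z); "zero": they are removed, which makes the lossless
        propagator unitary on the propagating subspace.
    reflection_passes
        Number of reflection marching passes added to the forward solve.
    edge_taper_width
        Width (voxels) of the raised-cosine roll-off applied to the field
        edge once on entry, before padding.
    """

    pad_fraction: float = 0.25
    evanescent_mode: str = "decay"
    reflection_passes: int = 2
    edge_taper_width: int = 16

    def __post_init__(self) -> None:
        if self.pad_fraction < 0:
            raise ValueError("pad_fraction must be >= 0")
        if self.evanescent_mode not in ("decay", "zero"):
            raise ValueError("evanescent_mode must be 'decay' or 'zero'")
        if self.reflection_passes < 0:
            raise ValueError("reflection_passes must be >= 0")


# ---------------------------------------------------------------------------
# spectral kernel


def _kz_grid(shape, pixel_mm, k_complex, distance_mm, mode):
    """Transfer function H = e^{−j k_z d} on the FFT grid.

    Evanescent handling: 'zero' removes components with
    k_x²+k_y² > Re(k)²; 'decay' forces them to decay regardless of the
    propagation direction (|H| <= 1 on the evanescent subspace).
    """
    d = distance_mm * 1e-3
    kx = 2 * np.pi * sfft.fftfreq(shape[0], d=pixel_mm * 1e-3)
    ky = 2 * np.pi * sfft.fftfreq(shape[1], d=pixel_mm * 1e-3)
    kr2 = kx[:, None] ** 2 + ky[None, :] ** 2
    kz = np.sqrt(k_complex**2 - kr2 + 0j)
    evan = kr2 > k_complex.real**2
    if mode == "zero":
        H = np.exp(-1j * kz * d)
        H[evan] = 0.0
    else:
        sgn = 1.0 if d >= 0 else -1.0
        kz = np.where(evan, kz.real - 1j * sgn * np.abs(kz.imag), kz)
        H = np.exp(-1j * kz * d)
    return H


def _taper_window(n: int, width: int) -> np.ndarray:
    w = np.ones(n)
    width = min(width, n // 2)
    if width > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * (np.arange(width) + 0.5) / width))
        w[:width] = ramp
        w[-width:] = ramp[::-1]
    return w


def _prepare_field(values: np.ndarray, settings: PropagationSettings):
    """Apply the edge taper and zero-pad; return (padded, crop slices)."""
    nx, ny = values.shape
    if settings.edge_taper_width > 0:
        values = (values
                  * _taper_window(nx, settings.edge_taper_width)[:, None]
                  * _taper_window(ny, settings.edge_taper_width)[None, :])
    px = int(round(nx * settings.pad_fraction))
    py = int(round(ny * settings.pad_fraction))
    padded = np.pad(values, ((px, px), (py, py)))
    return padded, (slice(px, px + nx), slice(py, py + ny))


# ---------------------------------------------------------------------------
# homogeneous operations


def angular_spectrum_step(
    plane: ComplexPressurePlane,
    distance: float,
    speed: float,
    attenuation: float = 0.0,
    evanescent_mode: str = "decay",
) -> ComplexPressurePlane:
    """Propagate a plane by ``distance`` mm through a uniform medium.

    Uses the complex wavenumber k = 2πf/c − jα so absorption is applied
    along each plane-wave component's oblique path.  ``distance`` may be
    negative (back-propagation).
    """
    vals = plane.values
    if not np.all(np.isfinite(vals.view(float))):
        raise ValueError("input field contains NaN/Inf")
    k = 2 * np.pi * plane.frequency / speed - 1j * attenuation
    H = _kz_grid(vals.shape, plane.pixel_size, k, distance, evanescent_mode)
    out = sfft.ifft2(sfft.fft2(vals) * H)
    return ComplexPressurePlane(out, plane.pixel_size,
                                plane.plane_z + distance, plane.frequency,
                                origin_xy=plane.origin_xy.copy())


def expand_plane_to_volume(
    plane: ComplexPressurePlane,
    z_targets,
    speed: float,
    attenuation: float = 0.0,
    settings: PropagationSettings | None = None,
) -> ComplexPressureVolume:
    """Stack angular-spectrum propagations of one plane to several z planes.

    The plane is tapered and padded once, its spectrum computed once, and
    each target plane obtained with a single transfer-function product, so
    the result at z is identical (to round-off) to repeated stepping.
    """
    settings = settings or PropagationSettings()
    z_targets = np.atleast_1d(np.asarray(z_targets, dtype=float))
    padded, crop = _prepare_field(plane.values, settings)
    spec = sfft.fft2(padded)
    k = 2 * np.pi * plane.frequency / speed - 1j * attenuation
    out = np.empty(plane.values.shape + (len(z_targets),), dtype=complex)
    for i, z in enumerate(z_targets):
        H = _kz_grid(padded.shape, plane.pixel_size, k, z - plane.plane_z,
                     settings.evanescent_mode)
        out[:, :, i] = sfft.ifft2(spec * H)[crop]
    origin = np.array([plane.origin_xy[0], plane.origin_xy[1], z_targets[0]])
    dz = z_targets[1] - z_targets[0] if len(z_targets) > 1 else plane.pixel_size
    return ComplexPressureVolume(out, dz, origin, plane.frequency)


# ---------------------------------------------------------------------------
# heterogeneous split-step propagation


def _check_source(model: VoxelModel, source: ComplexPressurePlane) -> None:
    if abs(source.frequency - model.frequency) > 1e-6 * model.frequency:
        raise ValueError(
            f"source frequency {source.frequency} Hz does not match model "
            f"frequency {model.frequency} Hz")
    if source.values.shape != model.shape[:2]:
        raise ValueError(
            f"source plane shape {source.values.shape} does not match model "
            f"transverse shape {model.shape[:2]}")
    if abs(source.pixel_size - model.voxel_size) > 1e-9:
        raise ValueError("source pixel size must equal model voxel size")
    front = model.origin[2] - model.voxel_size / 2
    if abs(source.plane_z - front) > 1e-6:
        warnings.warn(
            f"source plane_z={source.plane_z} mm is not at the model front "
            f"face ({front} mm); treating it as registered to the front face",
            stacklevel=3)


def _pad_plane(arr: np.ndarray, crop) -> np.ndarray:
    """Edge-replicate a material plane out to the padded FFT grid."""
    sx, sy = crop
    return np.pad(arr, ((sx.start, sx.start), (sy.start, sy.start)),
                  mode="edge")


def has_propagate(
    model: VoxelModel,
    source: ComplexPressurePlane,
    settings: PropagationSettings | None = None,
) -> ComplexPressureVolume:
    """Split-step hybrid angular spectrum propagation through ``model``.

    The source plane must be registered to the model front face (half a
    voxel before the first voxel-center plane).  Output plane ``iz`` holds
    the field at the *back face* of voxel slab ``iz``, i.e. at
    z = front_face + (iz+1)·Δz; the returned volume's origin records this
    half-voxel z offset.  Reflection passes (``settings.reflection_passes``)
    are applied on top of the forward solve.
    """
    settings = settings or PropagationSettings()
    _check_source(model, source)
    if np.any(~np.isfinite(source.values)):
        raise ValueError("source field contains NaN/Inf")

    forward = _forward_sweep(model, source, settings)
    if settings.reflection_passes > 0:
        return reflection_pass(model, forward, settings)
    return forward


def _slab_factors(model, iz, dz_m, crop, backward=False):
    """Space-domain factor and planar-mean wavenumber for slab ``iz``."""
    w = 2 * np.pi * model.frequency
    c = model.speed[:, :, iz]
    a = model.attenuation[:, :, iz]
    k_plane = w / c
    kbar = float(np.mean(k_plane))          # arithmetic mean, unpadded plane
    dk = _pad_plane(k_plane - kbar, crop)
    alpha = _pad_plane(a, crop)
    sgn = -1.0 if backward else 1.0
    factor = np.exp(-1j * sgn * dk * dz_m - alpha * dz_m)
    return factor, kbar


def _forward_sweep(model, source, settings) -> ComplexPressureVolume:
    nz = model.shape[2]
    dz_mm = model.voxel_size
    dz_m = dz_mm * 1e-3
    field, crop = _prepare_field(source.values, settings)
    out = np.empty(model.shape, dtype=complex)
    for iz in range(nz):
        factor, kbar = _slab_factors(model, iz, dz_m, crop)
        field = field * factor
        H = _kz_grid(field.shape, dz_mm, kbar + 0j, dz_mm,
                     settings.evanescent_mode)
        field = sfft.ifft2(sfft.fft2(field) * H)
        out[:, :, iz] = field[crop]
    origin = model.origin + np.array([0.0, 0.0, dz_mm / 2])
    return ComplexPressureVolume(out, dz_mm, origin, model.frequency)


def _march(model, seeds, settings, backward):
    """One reflection marching pass.

    ``seeds[iz]`` is the complex field injected at plane iz (the back face
    of voxel iz).  Marches through the model accumulating and propagating
    the injected waves; returns (field volume, incident volume) where the
    incident volume holds, per plane, the arriving field *before* the local
    seed was added (needed to form the next pass's reflections without a
    spurious same-interface double reflection).
    """
    nz = model.shape[2]
    dz_mm = model.voxel_size
    dz_m = dz_mm * 1e-3
    nx, ny = model.shape[:2]
    dummy, crop = _prepare_field(np.zeros((nx, ny), dtype=complex), settings)
    field = np.zeros_like(dummy)
    out = np.zeros(model.shape, dtype=complex)
    inc = np.zeros(model.shape, dtype=complex)
    order = range(nz - 1, -1, -1) if backward else range(nz)
    first = True
    for iz in order:
        if not first:
            # propagate from the previous stored plane through the slab
            # between them: slab iz+1 when backward, slab iz when forward
            slab = iz + 1 if backward else iz
            factor, kbar = _slab_factors(model, slab, dz_m, crop,
                                         backward=backward)
            field = field * factor
            H = _kz_grid(field.shape, dz_mm, kbar + 0j,
                         -dz_mm if backward else dz_mm,
                         settings.evanescent_mode)
            field = sfft.ifft2(sfft.fft2(field) * H)
        first = False
        inc[:, :, iz] = field[crop]
        s = seeds.get(iz)
        if s is not None:
            padded = np.pad(
                s, ((crop[0].start, crop[0].start),
                    (crop[1].start, crop[1].start)))
            field = field + padded
        out[:, :, iz] = field[crop]
    return out, inc


def reflection_pass(
    model: VoxelModel,
    forward: ComplexPressureVolume,
    settings: PropagationSettings | None = None,
) -> ComplexPressureVolume:
    """Add reflection passes to a forward HAS solution.

    At every z-interface between voxel slabs, the normal-incidence Fresnel
    coefficient R = (Z₂−Z₁)/(Z₂+Z₁) is applied per voxel column to the
    incident field to seed a counter-propagating wave; each pass marches
    the seeded waves through the model with the split-step scheme, and a
    subsequent pass re-reflects them in the opposite direction.  All passes
    are summed coherently with the forward field.  For a uniform-impedance
    model every R vanishes and the result equals ``forward``.
    """
    settings = settings or PropagationSettings()
    n_pass = settings.reflection_passes
    if n_pass < 1:
        return forward
    Z = model.impedance
    nz = model.shape[2]
    # R at interface iz (between slab iz and slab iz+1) for a wave moving +z
    R_fwd = [(Z[:, :, iz + 1] - Z[:, :, iz])
             / (Z[:, :, iz + 1] + Z[:, :, iz]) for iz in range(nz - 1)]

    total = forward.values.copy()
    prev_inc = forward.values       # incident forward field at each plane
    going_backward = True
    for _ in range(n_pass):
        seeds = {}
        for iz in range(nz - 1):
            R = R_fwd[iz] if going_backward else -R_fwd[iz]
            s = prev_inc[:, :, iz] * R
            if np.any(s != 0):
                seeds[iz] = s
        if not seeds:
            break
        out, inc = _march(model, seeds, settings, backward=going_backward)
        total = total + out
        prev_inc = inc
        going_backward = not going_backward
    return ComplexPressureVolume(total, forward.voxel_size,
                                 forward.origin.copy(), forward.frequency)
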