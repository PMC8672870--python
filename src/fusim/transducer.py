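"""Phased-array transducer model and Rayleigh–Sommerfeld source computation.

The array is a set of circular piston elements on a spherical shell whose
center of curvature is the geometric focus; the default preset mirrors a
256-element therapy array (940 kHz, 100 mm focal length, 144 × 98 mm
rectangular aperture).  The exact physical element layout of such arrays is
proprietary, so elements are packed pseudo-randomly (seeded, deterministic)
without overlap inside the rectangular aperture footprint.

The complex source pressure on the model front plane is obtained with a
one-time Rayleigh–Sommerfeld integral

    p(r) = Σ_sub  (jωρ u ΔA / 2π) · e^{−jkd} e^{−αd} / d ,

each element being subdivided into sub-sources no farther apart than λ/4.
Fields are then scaled by a single real factor so the plane-integrated
intensity Σ |p|²/(2Z) ΔA matches a target acoustic power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .grids import ComplexPressurePlane

WATER_SPEED = 1482.0      # m/s, degassed water
WATER_DENSITY = 998.0     # kg/m³


@dataclass(frozen=True)
class TransducerSpec:
    frequency_Hz: float = 940e3
    focal_length_mm: float = 100.0
    aperture_mm: tuple[float, float] = (144.0, 98.0)
    n_elements: int = 256
    element_radius_mm: float = 2.5
    layout_seed: int = 0
    layout: str = "random"     # "random" | "single" | "grid"


@dataclass
class TransducerArray:
    """Element positions/areas/drives of a focused phased array.

    ``drives`` are complex normal-velocity phasors (m/s); positions are in
    mm with the transducer face center at the coordinate origin and the
    geometric focus on the +z axis at ``focal_length``.
    """

    positions: np.ndarray          # (n, 3) mm, on the focal sphere
    areas: np.ndarray              # (n,) mm²
    drives: np.ndarray             # (n,) complex, m/s
    frequency: float               # Hz
    focal_length: float            # mm
    aperture: tuple[float, float]  # mm
    element_radius: float = 0.0    # mm (0 = point-like)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        self.drives = np.asarray(self.drives, dtype=complex)
        n = len(self.positions)
        if self.positions.shape != (n, 3) or len(self.areas) != n \
                or len(self.drives) != n:
            raise ValueError("inconsistent element array lengths")
        if np.any(self.areas <= 0):
            raise ValueError("element areas must be positive")
        focus = np.array([0.0, 0.0, self.focal_length])
        r = np.linalg.norm(self.positions - focus, axis=1)
        if np.any(np.abs(r - self.focal_length) > 1e-6):
            raise ValueError("element centers must lie on the focal sphere")

    @property
    def geometric_focus(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.focal_length])


def _shell_z(x, y, F):
    """z of the spherical shell (center of curvature at the focus)."""
    return F - np.sqrt(F**2 - x**2 - y**2)


def make_array(spec: TransducerSpec = TransducerSpec()) -> TransducerArray:
    """Build a transducer array from a spec (deterministic for fixed seed)."""
    F = spec.focal_length_mm
    ax, ay = spec.aperture_mm
    r = spec.element_radius_mm
    n = spec.n_elements
    if spec.layout == "single":
        xy = np.zeros((1, 2))
        n = 1
    elif spec.layout == "grid":
        ncol = int(np.ceil(np.sqrt(n * ax / ay)))
        nrow = int(np.ceil(n / ncol))
        gx = np.linspace(-ax / 2 + r, ax / 2 - r, ncol)
        gy = np.linspace(-ay / 2 + r, ay / 2 - r, nrow)
        xy = np.stack(np.meshgrid(gx, gy, indexing="ij"), -1).reshape(-1, 2)[:n]
    elif spec.layout == "random":
        xy = _pack_random(n, ax, ay, r, spec.layout_seed)
    else:
        raise ValueError(f"unknown layout {spec.layout!r}")
    x, y = xy[:, 0], xy[:, 1]
    if np.any(x**2 + y**2 >= F**2):
        raise ValueError("aperture exceeds the focal sphere radius")
    pos = np.column_stack([x, y, _shell_z(x, y, F)])
    areas = np.full(len(pos), np.pi * r**2 if r > 0 else 1.0)
    drives = np.ones(len(pos), dtype=complex)
    return TransducerArray(pos, areas, drives, spec.frequency_Hz, F,
                           (ax, ay), element_radius=r)


def _pack_random(n, ax, ay, r, seed, gap=0.2, max_tries=20000):
    rng = np.random.default_rng(seed)
    lo = np.array([-ax / 2 + r, -ay / 2 + r])
    hi = np.array([ax / 2 - r, ay / 2 - r])
    if np.any(hi <= lo):
        raise ValueError("element radius too large for the aperture")
    placed = np.empty((0, 2))
    tries = 0
    min_d = 2 * r + gap
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"cannot pack {n} elements of radius {r} mm into "
                f"{ax} x {ay} mm aperture (placed {len(placed)})")
        cand = lo + rng.uniform(size=2) * (hi - lo)
        if len(placed) == 0 or np.min(
                np.linalg.norm(placed - cand, axis=1)) >= min_d:
            placed = np.vstack([placed, cand])
    return placed


def focus_phases(array: TransducerArray, target,
                 speed: float = WATER_SPEED) -> TransducerArray:
    """Return a copy of the array phased to focus at ``target`` (mm).

    Element phase is set to +k·(d − F) with d the element-to-target
    distance, so the e^{−jkd} propagation phases cancel and all element
    contributions arrive in phase at the target.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    target = np.asarray(target, dtype=float)
    k = 2 * np.pi * array.frequency / speed          # rad/m
    d = np.linalg.norm(array.positions - target, axis=1) * 1e-3
    F = array.focal_length * 1e-3
    drives = np.abs(array.drives) * np.exp(
        1j * (np.angle(array.drives) + k * (d - F)))
    return replace(array, drives=drives,
                   positions=array.positions.copy(),
                   areas=array.areas.copy())


# ---------------------------------------------------------------------------
# Rayleigh–Sommerfeld evaluation


def _subsources(array: TransducerArray, spacing_mm: float):
    """Subdivide each element into sub-sources (positions, ΔA, drive)."""
    F = array.focal_length
    pos_out, area_out, drive_out = [], [], []
    for p, A, u in zip(array.positions, array.areas, array.drives):
        r_el = array.element_radius
        if r_el <= 0 or spacing_mm >= 2 * r_el:
            pos_out.append(p[None, :])
            area_out.append(np.array([A]))
            drive_out.append(np.array([u]))
            continue
        m = int(np.ceil(2 * r_el / spacing_mm))
        cell = 2 * r_el / m
        g = (np.arange(m) - (m - 1) / 2) * cell
        gx, gy = np.meshgrid(g, g, indexing="ij")
        keep = gx**2 + gy**2 <= r_el**2
        sx = p[0] + gx[keep]
        sy = p[1] + gy[keep]
        sz = _shell_z(sx, sy, F)
        sub = np.column_stack([sx, sy, sz])
        # true shell surface element: projected cell / cos(inclination),
        # cosγ = sqrt(F² − ρ²)/F on the focal sphere; normalized so the
        # element's projected footprint keeps its nominal area A
        cosg = np.sqrt(F**2 - sx**2 - sy**2) / F
        areas = A / (len(sub) * cosg)
        pos_out.append(sub)
        area_out.append(areas)
        drive_out.append(np.full(len(sub), u))
    return (np.concatenate(pos_out), np.concatenate(area_out),
            np.concatenate(drive_out))


def rs_field_at_points(
    array: TransducerArray,
    points,
    speed: float = WATER_SPEED,
    density: float = WATER_DENSITY,
    attenuation: float = 0.0,
    subsource_spacing: float | None = None,
    chunk: int = 512,
) -> np.ndarray:
    """Complex pressure (Pa) at arbitrary points by direct RS summation.

    ``subsource_spacing`` defaults to λ/4; observation points closer than
    a tenth of the spacing to any sub-source are excluded (set to NaN) with
    a warning.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    lam_mm = speed / array.frequency * 1e3
    spacing = subsource_spacing if subsource_spacing else lam_mm / 4
    spos, sarea, sdrive = _subsources(array, spacing)
    w = 2 * np.pi * array.frequency
    k = w / speed
    # per-subsource complex strength jωρ u ΔA / 2π (ΔA in m²)
    strength = 1j * w * density * sdrive * sarea * 1e-6 / (2 * np.pi)
    out = np.empty(len(points), dtype=complex)
    too_close = spacing * 0.1 * 1e-3
    hit_close = False
    sx, sy, sz = spos[:, 0], spos[:, 1], spos[:, 2]
    for s in range(0, len(points), chunk):
        P = points[s:s + chunk]
        d2 = (P[:, 0, None] - sx) ** 2
        d2 += (P[:, 1, None] - sy) ** 2
        d2 += (P[:, 2, None] - sz) ** 2
        d = np.sqrt(d2, out=d2) * 1e-3
        close = d < too_close
        if np.any(close):
            hit_close = True
            d = np.where(close, np.inf, d)
        phase = d * (-1j * k - attenuation)
        np.exp(phase, out=phase)
        phase *= strength
        phase /= d
        out[s:s + chunk] = phase.sum(axis=1)
    if hit_close:
        warnings.warn("observation points coincident with sub-sources were "
                      "excluded from the summation", stacklevel=2)
    return out


def rayleigh_sommerfeld(
    array: TransducerArray,
    plane_z: float,
    nx: int,
    ny: int,
    pixel_size: float,
    speed: float = WATER_SPEED,
    density: float = WATER_DENSITY,
    attenuation: float = 0.0,
    center_xy=(0.0, 0.0),
    subsource_spacing: float | None = None,
) -> ComplexPressurePlane:
    """Evaluate the RS integral of the array onto a transverse plane.

    The plane is an ``nx × ny`` grid of ``pixel_size`` mm pixels at
    ``plane_z`` mm, centered on ``center_xy``.
    """
    cx, cy = center_xy
    x = cx + (np.arange(nx) - (nx - 1) / 2) * pixel_size
    y = cy + (np.arange(ny) - (ny - 1) / 2) * pixel_size
    xx, yy = np.meshgrid(x, y, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(),
                           np.full(xx.size, plane_z)])
    vals = rs_field_at_points(array, pts, speed, density, attenuation,
                              subsource_spacing).reshape(nx, ny)
    return ComplexPressurePlane(vals, pixel_size, plane_z, array.frequency,
                                origin_xy=np.array([x[0], y[0]]))


def plane_power(plane: ComplexPressurePlane, impedance: float) -> float:
    """Plane-integrated acoustic power (W), plane-wave approximation."""
    pixel_area_m2 = (plane.pixel_size * 1e-3) ** 2
    return float(np.sum(np.abs(plane.values) ** 2) / (2 * impedance)
                 * pixel_area_m2)


def scale_to_power(
    plane: ComplexPressurePlane,
    impedance: float,
    target_power: float,
    edge_tolerance: float = 0.01,
) -> ComplexPressurePlane:
    """Scale a source plane so its integrated power equals ``target_power``.

    Refuses if the beam is clipped: the largest |p| on the plane boundary
    must stay below ``edge_tolerance`` of the global maximum so the
    plane-integrated intensity captures the whole beam.
    """
    if target_power <= 0:
        raise ValueError("target_power must be positive")
    mag = np.abs(plane.values)
    peak = mag.max()
    if peak == 0:
        raise ValueError("cannot scale an all-zero plane")
    edge = max(mag[0, :].max(), mag[-1, :].max(),
               mag[:, 0].max(), mag[:, -1].max())
    if edge > edge_tolerance * peak:
        raise ValueError(
            f"beam is clipped at the plane edge (edge |p| = {edge:.3g} Pa, "
            f"{edge / peak:.1%} of peak); enlarge the plane before scaling")
    current = plane_power(plane, impedance)
    factor = float(np.sqrt(target_power / current))
    return ComplexPressurePlane(plane.values * factor, plane.pixel_size,
                                plane.plane_z, plane.frequency,
                                origin_xy=plane.origin_xy.copy())
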