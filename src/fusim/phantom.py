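"""Synthetic voxelized phantom models.

Builds label maps for cylindrical tissue-mimicking phantoms — a gelatin
cylinder immersed in water, optionally containing canola-oil balloon
inclusions — and converts them to acoustic :class:`~fusim.grids.VoxelModel`
grids by material-table lookup.  These synthetic label maps stand in for
MRI-segmented models: geometry is exact instead of image-derived, but the
material assignment pipeline is identical.

Voxel membership uses a center-point test (no partial-volume averaging), so
label counts are deterministic for fixed inputs and rasterized volumes
converge to the analytic solid volume as the voxel size shrinks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .grids import LabelMap, VoxelModel
from .materials import DEFAULT_MATERIALS, MaterialProperties, scale_attenuation

SURROUND_LABEL = 0
HOST_LABEL = 1


@dataclass(frozen=True)
class InclusionSpec:
    """An ellipsoidal (or spherical) inclusion inside the host cylinder."""

    shape: str                  # "sphere" | "ellipsoid"
    center: tuple[float, float, float]   # mm
    semi_axes: tuple[float, float, float]  # mm (sphere: all equal)
    material: str

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "ellipsoid"):
            raise ValueError(f"unknown inclusion shape {self.shape!r}")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi_axes must be positive")
        if self.shape == "sphere" and len(set(self.semi_axes)) != 1:
            raise ValueError("sphere requires equal semi_axes")


def build_cylinder_phantom(
    diameter: float,
    height: float,
    host: str = "gelatin_70",
    inclusions: Sequence[InclusionSpec] = (),
    voxel_size: float = 0.5,
    surround: str = "water",
    front_z: float = 0.0,
    transverse_margin: float = 0.0,
    table: Mapping[str, MaterialProperties] = DEFAULT_MATERIALS,
) -> LabelMap:
    """Rasterize a cylindrical phantom with inclusions into a label map.

    The cylinder axis is the beam (z) axis, centered at x = y = 0, front
    face at ``front_z`` (mm).  The grid spans the cylinder diameter plus
    ``transverse_margin`` per side transversely, and the cylinder height
    axially; voxels outside the cylinder are labeled ``surround``.
    Inclusions override host, host overrides surround.  Inclusions that
    extend beyond the host cylinder are clipped with a warning.
    """
    if voxel_size <= 0 or diameter <= 0 or height <= 0:
        raise ValueError("voxel_size, diameter and height must be positive")
    for inc in inclusions:
        if inc.material not in table:
            raise KeyError(f"inclusion material {inc.material!r} not in table")
    if host not in table or surround not in table:
        raise KeyError("host/surround material not in table")

    half_xy = diameter / 2.0 + transverse_margin
    nxy = int(np.ceil(2 * half_xy / voxel_size))
    nz = int(np.ceil(height / voxel_size))
    # voxel centers, x/y symmetric about 0, z starting half a voxel past front_z
    x = (np.arange(nxy) - (nxy - 1) / 2.0) * voxel_size
    z = front_z + (np.arange(nz) + 0.5) * voxel_size
    origin = np.array([x[0], x[0], z[0]])

    xx, yy = np.meshgrid(x, x, indexing="ij")
    in_cyl2d = xx**2 + yy**2 <= (diameter / 2.0) ** 2

    labels = np.zeros((nxy, nxy, nz), dtype=np.int16)
    labels[in_cyl2d, :] = HOST_LABEL

    label_key = {SURROUND_LABEL: surround, HOST_LABEL: host}
    next_label = 2
    material_label: dict[str, int] = {}
    for inc in inclusions:
        if inc.material not in material_label:
            material_label[inc.material] = next_label
            label_key[next_label] = inc.material
            next_label += 1
        lab = material_label[inc.material]
        cx, cy, cz = inc.center
        ax, ay, az = inc.semi_axes
        inside = (
            ((xx[:, :, None] - cx) / ax) ** 2
            + ((yy[:, :, None] - cy) / ay) ** 2
            + ((z[None, None, :] - cz) / az) ** 2
        ) <= 1.0
        clipped = inside & (labels == SURROUND_LABEL)
        if np.any(clipped):
            warnings.warn(
                f"inclusion {inc.material!r} at {inc.center} extends outside "
                "the host cylinder and was clipped", stacklevel=2)
        labels[inside & (labels != SURROUND_LABEL)] = lab

    return LabelMap(labels=labels, voxel_size=voxel_size, origin=origin,
                    label_key=label_key)


def assign_properties(
    label_map: LabelMap,
    table: Mapping[str, MaterialProperties] = DEFAULT_MATERIALS,
    frequency: float = 940e3,
) -> VoxelModel:
    """Convert a label map to acoustic property grids at ``frequency``.

    Attenuation is scaled from its 1-MHz table value to the operating
    frequency (linear in frequency) and converted to Np/m.  Materials
    without thermal properties are accepted here; the thermal solver
    re-checks when they are actually heated.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    labels = label_map.labels
    speed = np.empty(labels.shape, dtype=float)
    atten = np.empty(labels.shape, dtype=float)
    dens = np.empty(labels.shape, dtype=float)
    for lab in np.unique(labels):
        name = label_map.label_key[int(lab)]
        if name not in table:
            raise KeyError(f"material {name!r} not in table")
        m = table[name]
        mask = labels == lab
        speed[mask] = m.speed_of_sound
        atten[mask] = scale_attenuation(m.attenuation_1MHz, frequency)
        dens[mask] = m.density
    return VoxelModel(speed=speed, attenuation=atten, density=dens,
                      voxel_size=label_map.voxel_size,
                      origin=label_map.origin.copy(), frequency=frequency)


def uniform_model(
    material: str,
    shape: tuple[int, int, int],
    voxel_size: float,
    frequency: float = 940e3,
    origin=(0.0, 0.0, 0.0),
    table: Mapping[str, MaterialProperties] = DEFAULT_MATERIALS,
) -> VoxelModel:
    """Homogeneous model of a single material (convenience constructor)."""
    m = table[material]
    full = np.full(shape, 1.0)
    return VoxelModel(
        speed=full * m.speed_of_sound,
        attenuation=full * scale_attenuation(m.attenuation_1MHz, frequency),
        density=full * m.density,
        voxel_size=voxel_size, origin=np.asarray(origin, float),
        frequency=frequency)


# -- presets ---------------------------------------------------------------

#: phantom presets: (diameter mm, height mm, heterogeneous?)
PRESETS = {
    "p-type-hom": (102.0, 30.0, False),
    "p-type-het": (102.0, 30.0, True),
    "t-type-het": (102.0, 150.0, True),
    "water": (102.0, 30.0, False),       # all-water control model
}


def preset_phantom(
    preset: str,
    milk: int = 70,
    voxel_size: float = 0.5,
    seed: int = 0,
    front_z: float = 50.0,
    n_inclusions: int = 5,
    table: Mapping[str, MaterialProperties] = DEFAULT_MATERIALS,
) -> LabelMap:
    """Build a preset phantom with seeded pseudo-random oil inclusions.

    Heterogeneous presets always use the 70%-milk gelatin host (chosen for
    maximum acoustic contrast with the oil); homogeneous presets take the
    milk fraction from ``milk`` (30/50/70).  Inclusion number, sizes and
    positions are illustrative: the build places ``n_inclusions``
    non-overlapping oil ellipsoids of 8–20 mm extent at seeded positions
    inside the cylinder.
    """
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    diameter, height, het = PRESETS[preset]
    if het:
        host = "gelatin_70"
        inclusions = _random_inclusions(
            diameter, height, front_z, n_inclusions, seed)
    elif preset == "water":
        host = "water"
        inclusions = []
    else:
        if milk not in (30, 50, 70):
            raise ValueError("milk fraction must be one of 30, 50, 70")
        host = f"gelatin_{milk}"
        inclusions = []
    return build_cylinder_phantom(
        diameter, height, host=host, inclusions=inclusions,
        voxel_size=voxel_size, front_z=front_z, table=table)


def _random_inclusions(diameter, height, front_z, n, seed,
                       material="canola_oil"):
    """Seeded non-overlapping ellipsoidal inclusions inside the cylinder."""
    rng = np.random.default_rng(seed)
    placed: list[InclusionSpec] = []
    tries = 0
    while len(placed) < n and tries < 1000:
        tries += 1
        semi = rng.uniform(4.0, 10.0, size=3)
        r_max = max(semi)
        # keep the bounding sphere inside the cylinder
        rho_lim = diameter / 2.0 - r_max
        z_lo = front_z + r_max
        z_hi = front_z + height - r_max
        if rho_lim <= 0 or z_hi <= z_lo:
            continue
        rho = rho_lim * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        center = (rho * np.cos(th), rho * np.sin(th), rng.uniform(z_lo, z_hi))
        ok = all(
            np.linalg.norm(np.subtract(center, p.center))
            > r_max + max(p.semi_axes)
            for p in placed)
        if ok:
            placed.append(InclusionSpec("ellipsoid", tuple(center),
                                        tuple(semi), material))
    if len(placed) < n:
        warnings.warn(f"placed only {len(placed)} of {n} inclusions")
    return placed
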