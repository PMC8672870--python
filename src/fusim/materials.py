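"""Acoustic and thermal material properties for phantom models.

Properties follow the convention of through-transmission phantom
characterization: speed of sound in m/s, amplitude attenuation in Np/cm
referenced to 1.0 MHz, density in kg/m³, thermal conductivity in W/m/°C and
specific heat in J/kg/°C.  Attenuation is an *amplitude* coefficient (a plane
wave decays as e^{-αz} with α in Np per unit length), and is assumed to scale
linearly with frequency with exponent 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping


@dataclass(frozen=True)
class MaterialProperties:
    """Bulk properties of one phantom material.

    Thermal fields may be ``None`` for acoustic-only materials, but must be
    present before the material is used in a thermal simulation.
    """

    name: str
    speed_of_sound: float        # m/s
    attenuation_1MHz: float      # Np/cm at 1.0 MHz (amplitude)
    density: float               # kg/m³
    thermal_conductivity: float | None = None  # W/m/°C
    specific_heat: float | None = None         # J/kg/°C

    def __post_init__(self) -> None:
        if self.speed_of_sound <= 0:
            raise ValueError(f"{self.name}: speed_of_sound must be > 0")
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be > 0")
        if self.attenuation_1MHz < 0:
            raise ValueError(f"{self.name}: attenuation_1MHz must be >= 0")

    @property
    def impedance(self) -> float:
        """Characteristic acoustic impedance Z = ρc (Rayl)."""
        return self.density * self.speed_of_sound

    @property
    def has_thermal(self) -> bool:
        return self.thermal_conductivity is not None and self.specific_heat is not None

    @property
    def volumetric_heat_capacity(self) -> float:
        """ρ·c_p in J/m³/°C; raises if thermal properties are absent."""
        if not self.has_thermal:
            raise ValueError(f"{self.name}: thermal properties are not set")
        return self.density * self.specific_heat


def scale_attenuation(alpha_1MHz: float, frequency: float) -> float:
    """Scale an attenuation coefficient from 1.0 MHz to ``frequency``.

    Parameters
    ----------
    alpha_1MHz : float
        Amplitude attenuation in Np/cm at 1.0 MHz.
    frequency : float
        Operating frequency in Hz.

    Returns
    -------
    float
        Amplitude attenuation in Np/m at ``frequency``, assuming attenuation
        linear in frequency (exponent fixed at 1).  The factor of 100
        converts Np/cm to Np/m.
    """
    if alpha_1MHz < 0:
        raise ValueError("attenuation must be non-negative")
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    return alpha_1MHz * (frequency / 1.0e6) * 100.0


#: Measured mean phantom-material properties.  Gelatin mixes are porcine
#: ballistics gelatin with evaporated milk at the stated volume fraction;
#: thermal values are only available for the 70% mix (the one used in the
#: heterogeneous phantoms) and for canola oil (literature values).
DEFAULT_MATERIALS: Mapping[str, MaterialProperties] = {
    "water": MaterialProperties(
        # degassed water at room temperature; attenuation negligible
        name="water", speed_of_sound=1482.0, attenuation_1MHz=0.0,
        density=998.0, thermal_conductivity=0.6, specific_heat=4186.0,
    ),
    "gelatin_30": MaterialProperties(
        name="gelatin_30", speed_of_sound=1552.7, attenuation_1MHz=0.027,
        density=1044.0,
    ),
    "gelatin_50": MaterialProperties(
        name="gelatin_50", speed_of_sound=1565.1, attenuation_1MHz=0.034,
        density=1052.0,
    ),
    "gelatin_70": MaterialProperties(
        name="gelatin_70", speed_of_sound=1578.5, attenuation_1MHz=0.056,
        density=1093.0, thermal_conductivity=0.534, specific_heat=3316.0,
    ),
    "canola_oil": MaterialProperties(
        name="canola_oil", speed_of_sound=1462.0, attenuation_1MHz=0.008,
        density=940.0, thermal_conductivity=0.184, specific_heat=1913.0,
    ),
}


def load_material_table(path) -> dict[str, MaterialProperties]:
    """Read a material table from a YAML config file.

    The file maps material name to a record with fields named as in
    :class:`MaterialProperties`; missing thermal fields are allowed.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    table = {}
    for name, rec in raw.items():
        table[name] = MaterialProperties(
            name=name,
            speed_of_sound=float(rec["speed_of_sound"]),
            attenuation_1MHz=float(rec["attenuation_1MHz"]),
            density=float(rec["density"]),
            thermal_conductivity=(None if rec.get("thermal_conductivity") is None
                                  else float(rec["thermal_conductivity"])),
            specific_heat=(None if rec.get("specific_heat") is None
                           else float(rec["specific_heat"])),
        )
    return table


def dump_material_table(table: Mapping[str, MaterialProperties], path) -> None:
    import yaml

    raw = {
        m.name: {
            "speed_of_sound": m.speed_of_sound,
            "attenuation_1MHz": m.attenuation_1MHz,
            "density": m.density,
            "thermal_conductivity": m.thermal_conductivity,
            "specific_heat": m.specific_heat,
        }
        for m in table.values()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh)
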