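"""Lattice constants, thermal corrections and d-spacings for calibration materials.

The calibration standards supported out of the box are the ones in routine
cryoEM use: fcc gold (the foil of UltrAuFoil/HexAuFoil supports), hcp gold
(a second lattice form present in some commercial foils, recognisable by its
(002) reflection at 2.48 Å), and graphitized carbon for low-magnification
work.  The fcc gold lattice constant carries a linear temperature
correction; below 43 K the constant is held fixed at the measured
low-temperature value of 4.0636 Å because thermal contraction flattens out
and the linear law no longer applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigurationError, InvalidReflectionError

__all__ = [
    "ThermalModel",
    "LatticeSpec",
    "Reflection",
    "MATERIALS",
    "d_spacing_cubic",
    "d_spacing_hexagonal",
    "gold_lattice_constant",
    "reflection_for",
    "get_material",
    "load_materials",
]


@dataclass(frozen=True)
class ThermalModel:
    """Linear temperature dependence of a lattice constant, clamped at low T.

    a(T) = a0 + slope * T for T >= clamp_temperature, and clamp_value below.
    The clamp introduces a discontinuity of about 1e-4 Å at the boundary
    (4.0611 + 5.67075e-5 * 43 = 4.06354 vs the clamp value 4.0636); this is
    deliberate — the clamp value is a measured constant, not a fit.
    """

    a0: float = 4.0611
    slope: float = 5.67075e-5
    clamp_temperature: float = 43.0
    clamp_value: float = 4.0636

    def evaluate(self, temperature_k: float) -> float:
        if temperature_k < 0:
            raise ValueError(f"temperature must be non-negative, got {temperature_k}")
        if temperature_k < self.clamp_temperature:
            return self.clamp_value
        return self.a0 + self.slope * temperature_k


@dataclass(frozen=True)
class LatticeSpec:
    """A crystalline calibration material.

    Parameters
    ----------
    material_id : str
        One of ``gold_fcc``, ``gold_hcp``, ``graphitized_carbon`` for the
        shipped catalogue; user catalogues may add ids.
    system : str
        ``cubic`` or ``hexagonal``.
    a, c : float
        Lattice constants in Å (``c`` only for hexagonal systems).
    thermal : ThermalModel, optional
        Temperature dependence of ``a``; absent means the constant is used
        as-is at any temperature.
    """

    material_id: str
    system: str
    a: float
    c: float | None = None
    thermal: ThermalModel | None = None

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError(f"lattice constant a must be positive, got {self.a}")
        if self.system == "hexagonal" and (self.c is None or self.c <= 0):
            raise ValueError("hexagonal lattice requires c > 0")
        if self.system not in ("cubic", "hexagonal"):
            raise ValueError(f"unsupported crystal system {self.system!r}")

    def lattice_constant(self, temperature_k: float) -> float:
        """Lattice constant ``a`` at the given temperature (Å)."""
        if self.thermal is None:
            return self.a
        return self.thermal.evaluate(temperature_k)


@dataclass(frozen=True)
class Reflection:
    """A Bragg reflection: Miller indices and the plane spacing d (Å)."""

    hkl: tuple[int, int, int]
    d: float

    @property
    def q(self) -> float:
        """Spatial frequency 1/d in 1/Å."""
        return 1.0 / self.d


#: Shipped material catalogue.  Graphitized carbon is parametrized as a cubic
#: lattice with a = 5.92 Å so its (111) spacing reproduces the 3.42 Å peak
#: measured at 81 K; it has no thermal model.  hcp gold likewise carries no
#: thermal correction.
MATERIALS: dict[str, LatticeSpec] = {
    "gold_fcc": LatticeSpec("gold_fcc", "cubic", a=4.0611, thermal=ThermalModel()),
    "gold_hcp": LatticeSpec("gold_hcp", "hexagonal", a=2.88, c=4.96),
    "graphitized_carbon": LatticeSpec("graphitized_carbon", "cubic", a=5.92),
}


def _check_hkl(hkl) -> tuple[int, int, int]:
    h, k, l = (int(v) for v in hkl)
    if h == 0 and k == 0 and l == 0:
        raise InvalidReflectionError("(0,0,0) is not a reflection")
    return h, k, l


def d_spacing_cubic(a: float, hkl) -> float:
    """Plane spacing of a cubic lattice: d = a / sqrt(h² + k² + l²).

    Parameters are the lattice constant ``a`` in Å and an integer Miller
    triple; returns d in Å.
    """
    if a <= 0:
        raise ValueError(f"lattice constant must be positive, got {a}")
    h, k, l = _check_hkl(hkl)
    return a / math.sqrt(h * h + k * k + l * l)


def d_spacing_hexagonal(a: float, c: float, hkl) -> float:
    """Plane spacing of a hexagonal lattice (three-index convention).

    1/d² = (4/3)(h² + hk + k²)/a² + l²/c².  Negative indices are accepted;
    note that under this formula d(1,-1,-1) = d(-1,-1,1), so the choice of
    sign convention for mixed indices does not matter.
    """
    if a <= 0 or c <= 0:
        raise ValueError("lattice constants must be positive")
    h, k, l = _check_hkl(hkl)
    inv_d2 = (4.0 / 3.0) * (h * h + h * k + k * k) / (a * a) + (l * l) / (c * c)
    return 1.0 / math.sqrt(inv_d2)


def gold_lattice_constant(temperature_k: float) -> float:
    """fcc gold lattice constant in Å at a specimen temperature in K.

    Linear in T down to 43 K; held at the measured 4.0636 Å below that,
    where thermal contraction has essentially stopped.
    """
    return MATERIALS["gold_fcc"].thermal.evaluate(temperature_k)


def get_material(material_id: str, catalogue: dict[str, LatticeSpec] | None = None) -> LatticeSpec:
    cat = MATERIALS if catalogue is None else catalogue
    try:
        return cat[material_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown material {material_id!r}; known: {sorted(cat)}"
        ) from None


def reflection_for(
    material_id: str,
    hkl,
    temperature_k: float = 81.0,
    catalogue: dict[str, LatticeSpec] | None = None,
) -> Reflection:
    """Reflection with its temperature-corrected d-spacing for a material.

    Materials without a thermal model (hcp gold, graphitized carbon) ignore
    the temperature and use their catalogue constants.
    """
    spec = get_material(material_id, catalogue)
    hkl = _check_hkl(hkl)
    a = spec.lattice_constant(temperature_k)
    if spec.system == "cubic":
        d = d_spacing_cubic(a, hkl)
    else:
        d = d_spacing_hexagonal(a, spec.c, hkl)
    return Reflection(hkl=hkl, d=d)


def load_materials(path: str | Path) -> dict[str, LatticeSpec]:
    """Load a user material catalogue from a YAML table.

    The file maps material ids to entries with keys ``system``, ``a``,
    optional ``c`` and optional ``thermal`` (``a0``, ``slope``,
    ``clamp_temperature``, ``clamp_value``).  Entries extend/override the
    shipped defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"material catalogue {path} is not a mapping")
    cat = dict(MATERIALS)
    for mid, entry in raw.items():
        thermal = None
        if entry.get("thermal"):
            thermal = ThermalModel(**entry["thermal"])
        cat[mid] = LatticeSpec(
            material_id=mid,
            system=entry["system"],
            a=float(entry["a"]),
            c=float(entry["c"]) if entry.get("c") is not None else None,
            thermal=thermal,
        )
    return cat
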