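"""Materials, projectiles and beam descriptions for charged-particle transport.

Compositions are mass-fraction based so that Bragg additivity can be applied
over elements; mean excitation energies are material-level (ICRU values), not
recombined from the elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ElementRef",
    "Material",
    "Projectile",
    "BeamSpec",
    "MaterialStack",
    "ELEMENTS",
    "WATER",
    "SUPER_FRICKE",
    "PMMA",
    "AIR",
    "PROTON",
    "CARBON",
    "builtin_material",
    "builtin_projectile",
]

#: atomic number Z and standard atomic weight A (g/mol) for the elements used
#: in the built-in materials.
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "Na": (11, 22.990),
    "S": (16, 32.06),
    "Cl": (17, 35.45),
    "Ar": (18, 39.948),
    "Fe": (26, 55.845),
}


@dataclass(frozen=True)
class ElementRef:
    """One element in a compound: symbol, Z, A and its mass fraction."""

    symbol: str
    z: int
    a: float
    mass_fraction: float


def _elements(fractions: dict[str, float]) -> tuple[ElementRef, ...]:
    refs = []
    for sym, w in fractions.items():
        if sym not in ELEMENTS:
            raise KeyError(f"unknown element symbol: {sym!r}")
        z, a = ELEMENTS[sym]
        refs.append(ElementRef(sym, z, a, w))
    return tuple(refs)


@dataclass(frozen=True)
class Material:
    """A homogeneous stopping medium.

    Parameters
    ----------
    name:
        Human-readable identifier.
    density:
        Mass density in g/cm^3.
    composition:
        Elements with mass fractions summing to 1.
    mean_excitation_energy:
        ICRU mean excitation energy I in eV, used directly in the Bethe
        logarithm (no element-wise recombination).
    """

    name: str
    density: float
    composition: tuple[ElementRef, ...]
    mean_excitation_energy: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if self.mean_excitation_energy <= 0:
            raise ValueError("mean excitation energy must be positive")
        total = sum(e.mass_fraction for e in self.composition)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions of {self.name} sum to {total}, not 1")

    @property
    def z_over_a(self) -> float:
        """Mass-fraction-weighted <Z/A> in mol/g (Bragg additivity)."""
        return sum(e.mass_fraction * e.z / e.a for e in self.composition)


@dataclass(frozen=True)
class Projectile:
    """A fully stripped ion: charge number z and rest mass in MeV."""

    name: str
    z: int
    rest_mass: float  # MeV
    mass_number: float = 1.0  # nucleon number, for MeV/u bookkeeping

    def __post_init__(self) -> None:
        if self.z < 1:
            raise ValueError("charge number must be >= 1")
        if self.rest_mass <= 0:
            raise ValueError("rest mass must be positive")


@dataclass(frozen=True)
class BeamSpec:
    """Beam at the accelerator exit window.

    mean_energy and energy_spread_sigma are total kinetic energies in MeV
    (not per nucleon); current is the electrical current in ampere, so the
    particle rate is current / (z * e).
    """

    projectile: Projectile
    mean_energy: float  # MeV (total kinetic)
    energy_spread_sigma: float = 0.0  # MeV
    current: float = 0.0  # A
    diameter: float = 8.0  # mm

    def __post_init__(self) -> None:
        if self.mean_energy <= 0:
            raise ValueError("mean energy must be positive")
        if self.energy_spread_sigma < 0:
            raise ValueError("energy spread must be >= 0")
        if self.current < 0:
            raise ValueError("current must be >= 0")
        if self.diameter <= 0:
            raise ValueError("beam diameter must be positive")


@dataclass(frozen=True)
class MaterialStack:
    """Ordered layers the beam crosses; exactly one is the observed sample."""

    layers: tuple[tuple[Material, float], ...]  # (material, thickness mm)
    sample_index: int = -1

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack needs at least one layer")
        for m, t in self.layers:
            if t <= 0:
                raise ValueError(f"layer {m.name} has non-positive thickness {t}")
        n = len(self.layers)
        idx = self.sample_index if self.sample_index >= 0 else n + self.sample_index
        if not 0 <= idx < n:
            raise ValueError("sample_index out of range")
        object.__setattr__(self, "sample_index", idx)

    @property
    def sample(self) -> tuple[Material, float]:
        return self.layers[self.sample_index]

    @property
    def upstream(self) -> tuple[tuple[Material, float], ...]:
        return self.layers[: self.sample_index]


# ---------------------------------------------------------------------------
# Built-ins

WATER = Material("water", 1.000, _elements({"H": 0.111894, "O": 0.888106}), 75.0)

#: Super-Fricke dosimeter solution: solutes are dilute, treated as water with
#: the measured solution density.
SUPER_FRICKE = Material(
    "super_fricke", 1.024, _elements({"H": 0.111894, "O": 0.888106}), 75.0
)

PMMA = Material(
    "pmma",
    1.190,
    _elements({"H": 0.080538, "C": 0.599848, "O": 0.319614}),
    74.0,
)

AIR = Material(
    "air",
    1.20479e-3,
    _elements({"C": 0.000124, "N": 0.755267, "O": 0.231781, "Ar": 0.012828}),
    85.7,
)

PROTON = Projectile("proton", z=1, rest_mass=938.272, mass_number=1.0)
CARBON = Projectile("carbon", z=6, rest_mass=11177.93, mass_number=12.0)

_MATERIALS = {m.name: m for m in (WATER, SUPER_FRICKE, PMMA, AIR)}
_PROJECTILES = {p.name: p for p in (PROTON, CARBON)}


def builtin_material(name: str) -> Material:
    try:
        return _MATERIALS[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; available: {sorted(_MATERIALS)}"
        ) from None


def builtin_projectile(name: str) -> Projectile:
    try:
        return _PROJECTILES[name]
    except KeyError:
        raise KeyError(
            f"unknown projectile {name!r}; available: {sorted(_PROJECTILES)}"
        ) from None
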