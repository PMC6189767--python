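"""Electrochemistry of patch-pipette and bath solutions.

This module turns salt recipes into free-ion compositions, evaluates the
Nernst equilibrium potential per ion, sums per-ion Nernst terms into the
multi-ion membrane battery, mixes an injected bolus into the cytoplasm by
instantaneous mass balance, and expresses the injection potential as the
post-injection minus pre-injection membrane battery.

Units: concentrations in mM, volumes in pL, temperatures in K, potentials
in mV. Concentrations are treated as fully dissociated free-ion values;
activity coefficients and buffer binding are out of scope.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)

#: Ideal gas constant, J K^-1 mol^-1.
GAS_CONSTANT = 8.314472
#: Faraday's constant, C mol^-1.
FARADAY = 9.648533e4
#: Default temperature (room temperature), K.
ROOM_TEMPERATURE_K = 298.15
#: Default cytoplasmic volume of a small adherent cell (ellipsoid with
#: diameter < 30 um and thickness < 10 um), pL. Configurable everywhere.
DEFAULT_CELL_VOLUME_PL = 2.5

# Stoichiometry of the salts used in the bath/pipette recipes: formula ->
# {ion: count per formula unit}.
SALT_STOICHIOMETRY: dict[str, dict[str, int]] = {
    "NaCl": {"Na+": 1, "Cl-": 1},
    "KCl": {"K+": 1, "Cl-": 1},
    "KF": {"K+": 1, "F-": 1},
    "NaF": {"Na+": 1, "F-": 1},
    "MgCl2": {"Mg2+": 1, "Cl-": 2},
    "CaCl2": {"Ca2+": 1, "Cl-": 2},
}

# Solutes that stay (effectively) undissociated at these pH values and are
# ignored by `dissociate` with a logged note; pH-adjustment bases (amounts
# unstated in the recipes) are treated the same way.
NON_DISSOCIATING: frozenset[str] = frozenset(
    {"glucose", "HEPES", "EGTA", "NaOH", "KOH"}
)

ION_VALENCES: dict[str, int] = {
    "Na+": 1,
    "K+": 1,
    "Mg2+": 2,
    "Ca2+": 2,
    "Cl-": -1,
    "F-": -1,
}


class UnknownSaltError(ValueError):
    """A salt formula without a stoichiometry entry."""


@dataclass(frozen=True)
class IonSpecies:
    """An ionic species: a label and a signed valence z (charge per ion)."""

    name: str
    valence: int

    def __post_init__(self) -> None:
        if self.valence == 0:
            raise ValueError(f"ion {self.name!r} must have nonzero valence")


SODIUM = IonSpecies("Na+", 1)
POTASSIUM = IonSpecies("K+", 1)
MAGNESIUM = IonSpecies("Mg2+", 2)
CALCIUM = IonSpecies("Ca2+", 2)
CHLORIDE = IonSpecies("Cl-", -1)
FLUORIDE = IonSpecies("F-", -1)


@dataclass(frozen=True)
class SaltRecipe:
    """A solution recipe as written on the bench: salts in mM.

    ``salts_mm`` preserves recipe order; duplicate formulas are summed at
    dissociation time.
    """

    salts_mm: tuple[tuple[str, float], ...]
    temperature_k: float = ROOM_TEMPERATURE_K
    label: str = ""

    def __post_init__(self) -> None:
        for formula, conc in self.salts_mm:
            if conc < 0:
                raise ValueError(
                    f"negative concentration {conc} mM for {formula!r}"
                )
        if self.temperature_k <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @classmethod
    def from_mapping(
        cls,
        salts_mm: Mapping[str, float],
        temperature_k: float = ROOM_TEMPERATURE_K,
        label: str = "",
    ) -> "SaltRecipe":
        return cls(tuple(salts_mm.items()), temperature_k, label)

    @classmethod
    def from_file(cls, path: str | Path) -> "SaltRecipe":
        """Load a recipe from a YAML key-value file (``*.cfg``)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "salts_mm" not in raw:
            raise ValueError(f"{path}: not a salt-recipe file (no salts_mm)")
        return cls.from_mapping(
            {str(k): float(v) for k, v in raw["salts_mm"].items()},
            temperature_k=float(raw.get("temperature_k", ROOM_TEMPERATURE_K)),
            label=str(raw.get("label", "")),
        )


@dataclass(frozen=True)
class IonicComposition:
    """Free-ion concentrations (mM) on one side of the membrane."""

    concentrations_mm: Mapping[str, float]
    temperature_k: float = ROOM_TEMPERATURE_K
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "concentrations_mm", dict(self.concentrations_mm)
        )
        for ion, conc in self.concentrations_mm.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {ion!r}: {conc}")
        if self.temperature_k <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    def get(self, ion: str | IonSpecies) -> float:
        name = ion.name if isinstance(ion, IonSpecies) else ion
        return self.concentrations_mm.get(name, 0.0)

    def __getitem__(self, ion: str | IonSpecies) -> float:
        return self.get(ion)

    def ions(self) -> tuple[str, ...]:
        return tuple(self.concentrations_mm)


def dissociate(recipe: SaltRecipe) -> IonicComposition:
    """Expand a salt recipe into its free-ion composition.

    Each ion's concentration is the stoichiometric sum over salts; solutes
    in :data:`NON_DISSOCIATING` are skipped with a logged note. An unknown
    formula raises :class:`UnknownSaltError`.
    """
    totals: dict[str, float] = {}
    for formula, conc_mm in recipe.salts_mm:
        if formula in NON_DISSOCIATING:
            logger.info(
                "recipe %r: ignoring non-dissociating solute %s (%g mM)",
                recipe.label, formula, conc_mm,
            )
            continue
        try:
            stoich = SALT_STOICHIOMETRY[formula]
        except KeyError:
            raise UnknownSaltError(
                f"no stoichiometry entry for salt formula {formula!r}"
            ) from None
        for ion, count in stoich.items():
            totals[ion] = totals.get(ion, 0.0) + conc_mm * count
    return IonicComposition(totals, recipe.temperature_k, recipe.label)


def nernst_potential(
    ion: IonSpecies,
    c_out_mm: float,
    c_in_mm: float,
    temperature_k: float = ROOM_TEMPERATURE_K,
) -> float:
    """Nernst equilibrium potential (RT / zF) ln(c_out / c_in), in mV."""
    if c_out_mm <= 0 or c_in_mm <= 0:
        raise ValueError(
            f"Nernst potential undefined for nonpositive concentration "
            f"({ion.name}: out={c_out_mm} mM, in={c_in_mm} mM)"
        )
    if temperature_k <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    volts = (
        GAS_CONSTANT * temperature_k / (ion.valence * FARADAY)
    ) * math.log(c_out_mm / c_in_mm)
    return volts * 1e3


def membrane_battery(
    outside: IonicComposition,
    inside: IonicComposition,
    ions: Sequence[IonSpecies],
) -> float:
    """Additive multi-ion membrane battery, in mV.

    The sum of per-ion Nernst terms over the listed ions (an additive sum,
    not a conductance-weighted GHK form). Ions whose contribution is judged
    negligible are excluded by the caller's ion list, never silently
    dropped here. With {Na+, K+} this is the two-ion battery used for the
    injection-potential estimate.
    """
    total = 0.0
    for ion in ions:
        c_out = outside.get(ion)
        c_in = inside.get(ion)
        if ion.name not in outside.concentrations_mm:
            raise ValueError(f"{ion.name} missing from outside composition")
        if ion.name not in inside.concentrations_mm:
            raise ValueError(f"{ion.name} missing from inside composition")
        total += nernst_potential(ion, c_out, c_in, outside.temperature_k)
    return total


def mix_injection(
    cytoplasm: IonicComposition,
    cell_volume_pl: float,
    injectate: IonicComposition,
    injected_volume_pl: float,
) -> IonicComposition:
    """Instantaneous conservative mixing of an injected bolus.

    Per ion, c_new = (c_cyto*V_cell + c_inj*V_inj) / (V_cell + V_inj).
    The bath composition is unaffected by injection (it is not an argument
    here on purpose).
    """
    if cell_volume_pl <= 0:
        raise ValueError("cell volume must be positive (pL)")
    if injected_volume_pl < 0:
        raise ValueError("injected volume must be non-negative (pL)")
    if injected_volume_pl == 0:
        return cytoplasm
    total = cell_volume_pl + injected_volume_pl
    ions = set(cytoplasm.concentrations_mm) | set(injectate.concentrations_mm)
    mixed = {
        ion: (
            cytoplasm.get(ion) * cell_volume_pl
            + injectate.get(ion) * injected_volume_pl
        )
        / total
        for ion in sorted(ions)
    }
    return IonicComposition(mixed, cytoplasm.temperature_k, cytoplasm.label)


def injection_potential(
    outside: IonicComposition,
    inside_old: IonicComposition,
    inside_new: IonicComposition,
    ions: Sequence[IonSpecies],
) -> float:
    """Injection potential: new minus old membrane battery, in mV.

    The hypothesized battery that appears when the injected solution shifts
    cytoplasmic concentrations while the bath stays unchanged.
    """
    return membrane_battery(outside, inside_new, ions) - membrane_battery(
        outside, inside_old, ions
    )
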