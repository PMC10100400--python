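"""Molecular formulae, monoisotopic masses and negative-mode adduct m/z.

Monoisotopic masses are computed as the sum of the most-abundant-isotope
mass of each element.  Deprotonation subtracts the mass of a *proton*
(1.0072765 Da), not of a hydrogen atom: the anion keeps the electron, and
this convention is what reproduces accurate-mass readings of deprotonated
ions on Orbitrap instruments to the fourth decimal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "MONOISOTOPIC",
    "PROTON_MASS",
    "WATER_MASS",
    "Adduct",
    "DEPROTONATED",
    "WATER_LOSS_DEPROTONATED",
    "DEFAULT_NEGATIVE_ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "neutral_mass",
]

# Most-abundant-isotope masses, IUPAC/CODATA, truncated to 7 decimals.
MONOISOTOPIC: dict[str, float] = {
    "C": 12.0000000,
    "H": 1.0078250,
    "N": 14.0030740,
    "O": 15.9949146,
    "P": 30.9737615,
    "S": 31.9720710,
    "Na": 22.9897693,
    "K": 38.9637065,
    "Cl": 34.9688527,
    "F": 18.9984032,
    "Se": 79.9165218,
    "I": 126.9044719,
}

PROTON_MASS = 1.0072765
WATER_MASS = 2 * MONOISOTOPIC["H"] + MONOISOTOPIC["O"]  # 18.0105646 Da

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when a molecular formula cannot be parsed."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation formula like ``C8H7N`` into element counts.

    Only flat formulae over known element symbols are accepted; an empty
    string parses to an empty composition (mass zero).
    """
    formula = formula.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _TOKEN.match(formula, pos)
        if m is None or m.start() != pos:
            raise FormulaError(f"unparsable formula {formula!r} at position {pos}")
        element, digits = m.groups()
        if element not in MONOISOTOPIC:
            raise FormulaError(f"unknown element {element!r} in formula {formula!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return counts


def monoisotopic_mass(formula: str | dict[str, int]) -> float:
    """Monoisotopic (most-abundant isotope) mass of a molecular formula, Da."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(MONOISOTOPIC[el] * n for el, n in counts.items())


@dataclass(frozen=True)
class Adduct:
    """A negative-mode ion adduct: observed m/z = (M + mass_shift) / |charge|."""

    name: str
    mass_shift: float
    charge: int = -1

    def mz(self, neutral_monoisotopic: float) -> float:
        return adduct_mz(neutral_monoisotopic, self)


DEPROTONATED = Adduct("[M-H]-", -PROTON_MASS)
WATER_LOSS_DEPROTONATED = Adduct("[M-H2O-H]-", -(WATER_MASS + PROTON_MASS))

#: The two adduct types considered for negative-mode annotation.
DEFAULT_NEGATIVE_ADDUCTS: tuple[Adduct, ...] = (DEPROTONATED, WATER_LOSS_DEPROTONATED)

_ADDUCTS_BY_NAME = {a.name: a for a in DEFAULT_NEGATIVE_ADDUCTS}


def get_adduct(name: str) -> Adduct:
    """Look up a bundled adduct by its bracket name, e.g. ``[M-H]-``."""
    try:
        return _ADDUCTS_BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown adduct {name!r}; known: {sorted(_ADDUCTS_BY_NAME)}") from None


def adduct_mz(neutral_monoisotopic: float, adduct: Adduct) -> float:
    """m/z of ``adduct`` formed from a neutral molecule of the given mass."""
    mz = (neutral_monoisotopic + adduct.mass_shift) / abs(adduct.charge)
    if mz <= 0:
        raise ValueError(
            f"adduct {adduct.name} of mass {neutral_monoisotopic:.4f} Da "
            f"yields non-positive m/z"
        )
    return mz


def neutral_mass(mz: float, adduct: Adduct) -> float:
    """Invert :func:`adduct_mz`: neutral monoisotopic mass of an observed ion."""
    return mz * abs(adduct.charge) - adduct.mass_shift


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error, (observed - theoretical)/theoretical x 1e6."""
    return (observed - theoretical) / theoretical * 1e6
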