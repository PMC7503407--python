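"""Elemental-formula arithmetic, monoisotopic masses and ppm errors.

Every downstream stage (scaffold assembly, fragment prediction, peak
annotation, networking) measures mass on the scale defined here: CODATA/
IUPAC monoisotopic atomic masses, hard-coded so results do not depend on
any external library version, and electron-corrected protonation, i.e. the
m/z of an [M+H]+ ion is neutral mass plus the *proton* mass (mass of H
minus one electron), not plus the mass of a hydrogen atom. High-resolution
instruments report m/z of cations, which have lost that electron; at the
sub-ppm level the distinction matters.
"""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterator, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "Formula",
    "parse_formula",
    "monoisotopic_mass",
    "protonated_mz",
    "ppm_error",
    "report_ppm",
]

#: Monoisotopic atomic masses in Da (most abundant isotope).
MONOISOTOPIC_MASS: Dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "F": 18.99840322,
    "Se": 79.9165213,
}

ELECTRON_MASS: float = 0.00054857990907
#: Mass of a proton: hydrogen atom minus its electron.
PROTON_MASS: float = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula(Mapping[str, int]):
    """Immutable element -> count map for a neutral molecule or ion.

    Supports ``+`` and ``-``; subtraction that would drive any count
    negative raises ``ValueError`` (a fragment cannot contain atoms its
    parent lacks). Zero counts are dropped, so two formulas are equal iff
    they denote the same multiset of atoms.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean: Dict[str, int] = {}
        for element, count in (counts or {}).items():
            if element not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {element!r}")
            if count < 0:
                raise ValueError(f"negative count for {element}: {count}")
            if count:
                clean[element] = int(count)
        self._counts = clean

    def __getitem__(self, element: str) -> int:
        return self._counts[element]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        return NotImplemented

    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for element, count in other._counts.items():
            counts[element] = counts.get(element, 0) + count
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for element, count in other._counts.items():
            new = counts.get(element, 0) - count
            if new < 0:
                raise ValueError(
                    f"subtraction would leave {new} atoms of {element}"
                )
            counts[element] = new
        return Formula(counts)

    def __mul__(self, n: int) -> "Formula":
        if n < 0:
            raise ValueError("multiplier must be non-negative")
        return Formula({e: c * n for e, c in self._counts.items()})

    __rmul__ = __mul__

    def __str__(self) -> str:
        return format_formula(self)

    def __repr__(self) -> str:
        return f"Formula({str(self)!r})"

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style element-count string, e.g. ``"C42H58N8O8"``.

    Counts default to 1 (``"H2O"`` -> {H: 2, O: 1}). Unknown element
    symbols and malformed strings raise ``ValueError``.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if not match.group(0):
            continue
        if match.start() != pos:
            raise ValueError(f"malformed formula string: {text!r}")
        element, digits = match.groups()
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"malformed formula string: {text!r}")
    return Formula(counts)


def format_formula(f: Mapping[str, int]) -> str:
    """Canonical Hill-notation writer: C, then H, then other elements
    alphabetically; count 1 is omitted."""
    parts = []
    order = [e for e in ("C", "H") if e in f]
    order += sorted(e for e in f if e not in ("C", "H"))
    for element in order:
        count = f[element]
        parts.append(element if count == 1 else f"{element}{count}")
    return "".join(parts)


def monoisotopic_mass(f: Mapping[str, int]) -> float:
    """Sum of count x monoisotopic atomic mass, in Da."""
    return sum(MONOISOTOPIC_MASS[e] * c for e, c in f.items())


def protonated_mz(neutral_mass: float, charge: int = 1) -> float:
    """m/z of an [M + zH]z+ ion: (M + z * proton) / z."""
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def report_ppm(signed_ppm: float) -> float:
    """Unsigned ppm error rounded half-up to one decimal, the convention
    used when tabulating product-ion assignments."""
    return float(
        Decimal(repr(abs(signed_ppm))).quantize(Decimal("0.1"), ROUND_HALF_UP)
    )
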