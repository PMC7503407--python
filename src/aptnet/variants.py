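"""Candidate structure enumeration under biosynthetic position constraints.

The adenylation domains of the apt gene cluster predict which residues each
scaffold position can carry: here the starter and third modules are
promiscuous for small hydrophobic residues (Val/Leu at X1, Val/Ile/Leu at
X3), Trp is fixed at X4, and Lys/MeAla/Phe are conserved. Enumerating the
Cartesian product of those allowed sets — collapsing the isobaric Ile/Leu
pair to one mass class — yields the candidate structures behind observed
precursor masses and the CH2-homolog mass shifts seen between network
nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Mapping, Sequence

import pandas as pd

from .chem import monoisotopic_mass, ppm_error, protonated_mz
from .scaffold import (
    POSITIONS,
    AptVariant,
    ResidueBlock,
    assemble_neutral_formula,
    default_block_library,
    make_variant,
)

__all__ = [
    "STUDY_CONSTRAINTS",
    "MassShiftExplanation",
    "enumerate_variants",
    "candidates_for_precursor",
    "explain_mass_shift",
    "variant_summary_table",
]

#: Allowed blocks per position for the Trp-containing anabaenopeptin family
#: (A-domain substrate predictions: Val/Leu at X1; Val/Ile/Leu at X3; Trp
#: fixed at X4; Lys, MeAla, Phe conserved).
STUDY_CONSTRAINTS: Dict[str, List[str]] = {
    "X1": ["Val", "Leu"],
    "X2": ["Lys"],
    "X3": ["Val", "Ile", "Leu"],
    "X4": ["Trp"],
    "X5": ["MeAla"],
    "X6": ["Phe"],
}

#: Names collapsed into one mass-equivalent class when merging is on.
XLE_CLASS = frozenset({"Ile", "Leu", "Ile/Leu"})


@dataclass(frozen=True)
class MassShiftExplanation:
    """One single-position substitution consistent with an observed Δm."""

    position: str
    from_block: str
    to_block: str
    theoretical_dm: float
    observed_dm: float

    @property
    def residual(self) -> float:
        return self.observed_dm - self.theoretical_dm


def _merged_name(name: str, merge_xle: bool) -> str:
    return "Ile/Leu" if merge_xle and name in XLE_CLASS else name


def enumerate_variants(
    constraints: Mapping[str, Sequence[str]] | None = None,
    library: Dict[str, ResidueBlock] | None = None,
    merge_xle: bool = True,
) -> List[AptVariant]:
    """All variants allowed by per-position constraints, in deterministic
    order (position-wise name tuples, X1 fastest-varying last).

    With ``merge_xle`` (the default) Ile and Leu collapse to the merged
    ``Ile/Leu`` block, so the result is deduplicated to mass-distinct
    structures as seen by MS.
    """
    constraints = dict(constraints) if constraints is not None else dict(STUDY_CONSTRAINTS)
    library = library if library is not None else default_block_library()
    for pos in POSITIONS:
        allowed = constraints.get(pos, [])
        if not allowed:
            raise ValueError(f"no allowed blocks at position {pos}")
        for name in allowed:
            if name not in library:
                raise ValueError(f"block {name!r} (position {pos}) not in library")
            if pos not in library[name].allowed_positions:
                raise ValueError(f"block {name!r} does not permit position {pos}")

    seen = set()
    variants: List[AptVariant] = []
    for combo in product(*(constraints[pos] for pos in POSITIONS)):
        names = tuple(_merged_name(n, merge_xle) for n in combo)
        if names in seen:
            continue
        seen.add(names)
        variants.append(make_variant(names, library))
    variants.sort(key=lambda v: tuple(r.name for r in v.residues))
    return variants


def candidates_for_precursor(
    mz: float,
    tol_ppm: float = 5.0,
    constraints: Mapping[str, Sequence[str]] | None = None,
    library: Dict[str, ResidueBlock] | None = None,
    merge_xle: bool = True,
) -> List[AptVariant]:
    """Enumerated variants whose [M+H]+ lies within ``tol_ppm`` of ``mz``."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    out = []
    for v in enumerate_variants(constraints, library, merge_xle):
        theo = protonated_mz(monoisotopic_mass(assemble_neutral_formula(v)))
        if abs(ppm_error(mz, theo)) <= tol_ppm:
            out.append(v)
    return out


def explain_mass_shift(
    dm: float,
    constraints: Mapping[str, Sequence[str]] | None = None,
    library: Dict[str, ResidueBlock] | None = None,
    tol: float = 0.02,
    merge_xle: bool = True,
) -> List[MassShiftExplanation]:
    """Single-position substitutions whose residue-mass difference matches
    an observed precursor Δm within ``tol`` Da (default 0.02 Da, the
    fragment-tolerance scale of the networking step)."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    constraints = dict(constraints) if constraints is not None else dict(STUDY_CONSTRAINTS)
    library = library if library is not None else default_block_library()
    out: List[MassShiftExplanation] = []
    seen = set()
    for pos in POSITIONS:
        names = sorted({_merged_name(n, merge_xle) for n in constraints.get(pos, [])})
        for a in names:
            for b in names:
                if a == b:
                    continue
                theo = library[b].mass - library[a].mass
                if abs(dm - theo) <= tol:
                    key = (pos, a, b)
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append(
                        MassShiftExplanation(
                            position=pos,
                            from_block=a,
                            to_block=b,
                            theoretical_dm=theo,
                            observed_dm=dm,
                        )
                    )
    out.sort(key=lambda e: (abs(e.residual), e.position, e.from_block, e.to_block))
    return out


def variant_summary_table(variants: Sequence[AptVariant]) -> pd.DataFrame:
    """Name, formula, neutral mass and [M+H]+ for a list of variants."""
    rows = []
    for v in variants:
        f = assemble_neutral_formula(v)
        mass = monoisotopic_mass(f)
        rows.append(
            {
                "name": v.name,
                "formula": str(f),
                "neutral_mass": mass,
                "mh_mz": protonated_mz(mass),
            }
        )
    return pd.DataFrame(rows, columns=["name", "formula", "neutral_mass", "mh_mz"])
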