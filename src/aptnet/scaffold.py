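"""Anabaenopeptin scaffold model and theoretical fragment generation.

Anabaenopeptins are cyclic hexapeptides with the general structure
``X1-CO-[Lys2-X3-X4-MeX5-X6]``: five residues form a ring closed between
the C-terminal carboxyl and the alpha-amine of a conserved Lys at position
2, while the sixth residue (X1) hangs off the Lys side via a ureido
(N-CO-N) bond, which contributes one CO beyond the residue masses. The
neutral molecule is therefore the sum of the six residue masses plus CO2
(six amide/ureido condensations leave one water-equivalent plus the ureido
carbonyl; the identity is checked as a property test).

Collision-induced dissociation of the protonated molecule produces three
fragment families, all singly protonated here:

* ``ring_b`` — b-type ions from contiguous runs of the ring that do not
  contain Lys (the ring opens at an amide and loses the ureido part);
  composition = sum of run residues + proton.
* ``ureido_series`` — ions retaining the ureido carbonyl: any residue set
  containing Lys that is contiguous in the molecule graph (the 5-ring plus
  the exocyclic X1 attached at Lys), with X1 optionally retained;
  composition = sum of residues + CO2 + proton. This one rule covers the
  ``CO-Lys-Phe-MeAla``-type ions, their X1-extended forms, and the
  Trp-loss ions ``X1-CO-Lys-(X3)-(Phe-MeAla)``.
* ``immonium`` — low-mass residue-diagnostic cations taken from the block
  library (Lys -> C5H10N+, Trp -> C9H8N+, MeAla+CO -> C5H8NO2+).

Ile and Leu are isobaric and indistinguishable by MS; the default library
carries them both plus a merged ``Ile/Leu`` block used when enumerating
mass-distinct candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Tuple

import pandas as pd

from .chem import (
    ELECTRON_MASS,
    Formula,
    monoisotopic_mass,
    parse_formula,
    protonated_mz,
)

__all__ = [
    "POSITIONS",
    "CO2",
    "ResidueBlock",
    "AptVariant",
    "TheoreticalFragment",
    "default_block_library",
    "make_variant",
    "assemble_neutral_formula",
    "generate_fragments",
    "fragment_table",
]

POSITIONS: Tuple[str, ...] = ("X1", "X2", "X3", "X4", "X5", "X6")

CO2 = parse_formula("CO2")
H2O = parse_formula("H2O")
_H = parse_formula("H")


@dataclass(frozen=True)
class ResidueBlock:
    """One building block: an amino-acid residue (free acid minus water).

    ``immonium`` holds diagnostic cation formulas observed for this
    residue, keyed by a display label; their m/z is the cation mass minus
    one electron.
    """

    name: str
    formula: Formula
    allowed_positions: FrozenSet[str]
    immonium: Tuple[Tuple[str, Formula], ...] = ()

    def __post_init__(self):
        bad = set(self.allowed_positions) - set(POSITIONS)
        if bad:
            raise ValueError(f"unknown scaffold positions: {sorted(bad)}")

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)


def default_block_library() -> Dict[str, ResidueBlock]:
    """Blocks needed for the Trp-containing anabaenopeptin family:
    Val/Leu/Ile (and the merged mass-class Ile/Leu) for the variable
    positions, plus the conserved Lys, Trp, N-methylalanine and Phe."""

    def block(name, formula, positions, immonium=()):
        return ResidueBlock(
            name=name,
            formula=parse_formula(formula),
            allowed_positions=frozenset(positions),
            immonium=tuple((lab, parse_formula(f)) for lab, f in immonium),
        )

    xle_positions = ("X1", "X3", "X5", "X6")
    return {
        "Val": block("Val", "C5H9NO", ("X1", "X3", "X5", "X6")),
        "Leu": block("Leu", "C6H11NO", xle_positions),
        "Ile": block("Ile", "C6H11NO", xle_positions),
        # Ile and Leu share C6H11NO; the merged block is what MS can see.
        "Ile/Leu": block("Ile/Leu", "C6H11NO", xle_positions),
        "Lys": block("Lys", "C6H12N2O", ("X2",), [("Lys fragment", "C5H10N")]),
        "Trp": block("Trp", "C11H10N2O", ("X4",), [("Trp fragment", "C9H8N")]),
        "MeAla": block(
            "MeAla", "C4H7NO", ("X5",), [("MeAla + CO + H+", "C5H8NO2")]
        ),
        "Phe": block("Phe", "C9H9NO", ("X6",)),
    }


@dataclass(frozen=True)
class AptVariant:
    """Assignment of one residue block to each scaffold position X1..X6.

    X2 must be Lys: the ureido bond and the ring closure both run through
    it, so the scaffold is not an anabaenopeptin otherwise. D-Lys
    stereochemistry (from the epimerization domain) is an annotation only;
    mass arithmetic is stereochemistry-blind.
    """

    residues: Tuple[ResidueBlock, ...]
    display_name: str = field(default="", compare=False)

    def __post_init__(self):
        if len(self.residues) != len(POSITIONS):
            raise ValueError(
                f"a variant needs exactly {len(POSITIONS)} residues, "
                f"got {len(self.residues)}"
            )
        for pos, res in zip(POSITIONS, self.residues):
            if pos not in res.allowed_positions:
                raise ValueError(f"{res.name} is not allowed at {pos}")
        if self.residues[1].name != "Lys":
            raise ValueError("position X2 must be Lys")

    def __getitem__(self, position: str) -> ResidueBlock:
        return self.residues[POSITIONS.index(position)]

    @property
    def name(self) -> str:
        if self.display_name:
            return self.display_name
        n = [r.name for r in self.residues]
        return f"{n[0]}-CO-[{n[1]}-{n[2]}-{n[3]}-{n[4]}-{n[5]}]"


def make_variant(
    names: Sequence[str],
    library: Dict[str, ResidueBlock] | None = None,
    display_name: str = "",
) -> AptVariant:
    """Build a variant from six block names (X1..X6) and a block library."""
    library = library if library is not None else default_block_library()
    if len(names) != len(POSITIONS):
        raise ValueError(f"expected {len(POSITIONS)} residue names, got {len(names)}")
    missing = [n for n in names if n not in library]
    if missing:
        raise ValueError(f"blocks not in library: {missing}")
    return AptVariant(
        residues=tuple(library[n] for n in names), display_name=display_name
    )


@dataclass(frozen=True)
class TheoreticalFragment:
    """A labeled product ion: cation composition plus theoretical m/z."""

    label: str
    series: str  # full_ion | ring_b | ureido_series | immonium
    ion_formula: Formula
    mz: float


def assemble_neutral_formula(v: AptVariant) -> Formula:
    """Neutral molecular formula: sum of the six residue formulas + CO2."""
    total = Formula()
    for res in v.residues:
        total = total + res.formula
    return total + CO2


def _protonated_fragment(label: str, series: str, neutral: Formula) -> TheoreticalFragment:
    ion = neutral + _H
    return TheoreticalFragment(
        label=label,
        series=series,
        ion_formula=ion,
        mz=monoisotopic_mass(ion) - ELECTRON_MASS,
    )


def generate_fragments(v: AptVariant) -> List[TheoreticalFragment]:
    """Theoretical singly-protonated product ions of a variant.

    Emits the full ion, all ring b-type ions, all ureido-series ions and
    the library immonium ions; the list is duplicate-free by
    (composition, label) and deterministically ordered (by m/z, then
    label).
    """
    x1 = v["X1"]
    ring = [v["X2"], v["X3"], v["X4"], v["X5"], v["X6"]]  # cycle, Lys first
    frags: List[TheoreticalFragment] = []

    # (a) full ion: all six residues + CO2, protonated
    full_label = v.name
    frags.append(
        _protonated_fragment(full_label, "full_ion", assemble_neutral_formula(v))
    )

    # (b) ring b series: contiguous runs of the ring path X3-X4-X5-X6
    # (the ring opened at Lys); both traversal directions give the same
    # residue sets, so runs of the linear path are exhaustive.
    path = ring[1:]
    for start in range(len(path)):
        for length in range(1, len(path) - start + 1):
            run = path[start : start + length]
            neutral = Formula()
            for res in run:
                neutral = neutral + res.formula
            label = "-".join(r.name for r in run)
            frags.append(_protonated_fragment(label, "ring_b", neutral))

    # (c) ureido series: arcs of the 5-ring containing Lys, with or
    # without the exocyclic X1; composition = residues + CO2. An arc is
    # parameterised by how far it extends clockwise (toward X3) and
    # counter-clockwise (toward X6) from Lys. The full ring with X1 is
    # the full ion and is not re-emitted.
    cw = ring[1:]  # X3, X4, X5, X6
    ccw = ring[:0:-1]  # X6, X5, X4, X3
    for a in range(len(cw) + 1):
        for b in range(len(cw) + 1 - a):
            arc = [ring[0]] + cw[:a] + ccw[:b]
            full_ring = a + b == len(cw)
            if full_ring and a != 0:
                continue  # keep a single (a, b) decomposition of the full ring
            neutral = CO2
            for res in arc:
                neutral = neutral + res.formula
            if full_ring:
                core = "[" + "-".join(r.name for r in ring) + "]"
            elif b == 0:
                core = "-".join(r.name for r in arc)
            elif a == 0:
                core = "Lys-" + "-".join(r.name for r in ccw[:b])
            else:
                core = (
                    "Lys-(" + "-".join(r.name for r in cw[:a]) + ")-("
                    + "-".join(r.name for r in ccw[:b]) + ")"
                )
            for with_x1 in (False, True):
                if with_x1 and full_ring:
                    continue  # identical to the full ion
                prefix = f"{x1.name}-CO-" if with_x1 else "CO-"
                frag_neutral = neutral + x1.formula if with_x1 else neutral
                frags.append(
                    _protonated_fragment(prefix + core, "ureido_series", frag_neutral)
                )

    # (d) immonium-type diagnostic cations from the block library
    seen_immonium = set()
    for res in v.residues:
        for label, cation in res.immonium:
            if (label, cation) in seen_immonium:
                continue
            seen_immonium.add((label, cation))
            frags.append(
                TheoreticalFragment(
                    label=label,
                    series="immonium",
                    ion_formula=cation,
                    mz=monoisotopic_mass(cation) - ELECTRON_MASS,
                )
            )

    unique: Dict[Tuple[Formula, str], TheoreticalFragment] = {}
    for frag in frags:
        unique.setdefault((frag.ion_formula, frag.label), frag)
    return sorted(unique.values(), key=lambda f: (f.mz, f.label))


def fragment_table(v: AptVariant) -> pd.DataFrame:
    """Fragment assignments as a table sorted by m/z ascending."""
    frags = generate_fragments(v)
    return pd.DataFrame(
        {
            "label": [f.label for f in frags],
            "series": [f.series for f in frags],
            "ion_formula": [str(f.ion_formula) for f in frags],
            "mz": [f.mz for f in frags],
        }
    ).sort_values("mz", kind="mergesort", ignore_index=True)
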