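"""Published product-ion observations for the Trp-containing APT family.

The three compounds — anabaenopeptin 788, 802 and 816 — were assigned
from high-resolution product-ion spectra; this module carries the
published observed m/z values (and the printed one-decimal ppm errors)
so the scaffold model can be validated against them: for every ion the
theoretical m/z is recomputed from the residue-sum rules and compared to
the observation.

A few printed error values are internally inconsistent and are flagged
``reliable=False``: the low-m/z diagnostic ions (84/114/130) carry
different printed errors at identical observed m/z across compounds, the
272.196 entry of compound 788 is three orders of magnitude off its own
error column, and the printed errors at 272.1394 (816), 518.2973 and
617.3677 cannot arise from any standard mass-scale convention given the
4-decimal precision of the observed values. Those rows are still
annotated; they are simply not usable as exact checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import pandas as pd

from .chem import ppm_error, report_ppm
from .scaffold import generate_fragments
from .simulate import study_family

__all__ = ["ProductIonObservation", "STUDY_PRODUCT_IONS", "product_ion_error_table"]


@dataclass(frozen=True)
class ProductIonObservation:
    compound: str  # APT788 | APT802 | APT816
    fragment_label: str  # label used by generate_fragments
    series: str
    observed_mz: float
    printed_ppm: float
    reliable: bool = True


STUDY_PRODUCT_IONS: List[ProductIonObservation] = [
    # low-m/z diagnostic ions: printed errors inconsistent across compounds
    ProductIonObservation("APT788", "Lys fragment", "immonium", 84.0810, 2.6, False),
    ProductIonObservation("APT802", "Lys fragment", "immonium", 84.0808, 0.7, False),
    ProductIonObservation("APT816", "Lys fragment", "immonium", 84.0808, 0.2, False),
    ProductIonObservation("APT788", "MeAla + CO + H+", "immonium", 114.0549, 0.1, False),
    ProductIonObservation("APT802", "MeAla + CO + H+", "immonium", 114.0551, 1.1, False),
    ProductIonObservation("APT816", "MeAla + CO + H+", "immonium", 114.0550, 0.0, False),
    ProductIonObservation("APT788", "Trp fragment", "immonium", 130.0650, 0.7, False),
    ProductIonObservation("APT802", "Trp fragment", "immonium", 130.0653, 1.0, False),
    ProductIonObservation("APT816", "Trp fragment", "immonium", 130.0651, 0.1, False),
    # ring b-type ions
    ProductIonObservation("APT788", "Trp-MeAla", "ring_b", 272.196, 0.6, False),
    ProductIonObservation("APT802", "Trp-MeAla", "ring_b", 272.1399, 2.1),
    ProductIonObservation("APT816", "Trp-MeAla", "ring_b", 272.1394, 0.6, False),
    ProductIonObservation("APT788", "Val-Trp-MeAla", "ring_b", 371.2087, 2.4),
    ProductIonObservation("APT802", "Ile/Leu-Trp-MeAla", "ring_b", 385.2249, 3.9),
    ProductIonObservation("APT816", "Ile/Leu-Trp-MeAla", "ring_b", 385.2234, 0.0),
    # ureido-series ions
    ProductIonObservation("APT788", "CO-Lys-Phe-MeAla", "ureido_series", 405.2141, 2.1),
    ProductIonObservation("APT802", "CO-Lys-Phe-MeAla", "ureido_series", 405.2143, 2.5),
    ProductIonObservation("APT816", "CO-Lys-Phe-MeAla", "ureido_series", 405.2138, 1.4),
    ProductIonObservation(
        "APT788", "Val-CO-Lys-Phe-MeAla", "ureido_series", 504.2811, 1.0
    ),
    ProductIonObservation(
        "APT802", "Val-CO-Lys-Phe-MeAla", "ureido_series", 504.2830, 2.7
    ),
    ProductIonObservation(
        "APT816", "Ile/Leu-CO-Lys-Phe-MeAla", "ureido_series", 518.2973, 3.0, False
    ),
    ProductIonObservation(
        "APT788", "Val-CO-Lys-(Val)-(Phe-MeAla)", "ureido_series", 603.3497, 0.6
    ),
    ProductIonObservation(
        "APT802", "Val-CO-Lys-(Ile/Leu)-(Phe-MeAla)", "ureido_series", 617.3677, 4.0, False
    ),
    ProductIonObservation(
        "APT816", "Ile/Leu-CO-Lys-(Ile/Leu)-(Phe-MeAla)", "ureido_series", 631.3797, 2.7
    ),
    # full ions
    ProductIonObservation(
        "APT788", "Val-CO-[Lys-Val-Trp-MeAla-Phe]", "full_ion", 789.4304, 1.3
    ),
    ProductIonObservation(
        "APT802", "Val-CO-[Lys-Ile/Leu-Trp-MeAla-Phe]", "full_ion", 803.4469, 2.3
    ),
    ProductIonObservation(
        "APT816", "Ile/Leu-CO-[Lys-Ile/Leu-Trp-MeAla-Phe]", "full_ion", 817.4612, 0.6
    ),
]


def product_ion_error_table() -> pd.DataFrame:
    """Recompute every published product-ion error from first principles.

    Columns: compound, label, series, observed m/z, theoretical m/z
    (residue-sum composition, electron-corrected protonation), signed ppm,
    recomputed one-decimal |ppm|, the printed |ppm| and the reliability
    flag.
    """
    family = study_family()
    fragment_index: Dict[tuple, float] = {}
    for compound, variant in family.items():
        for frag in generate_fragments(variant):
            fragment_index[(compound, frag.label, frag.series)] = frag.mz
    rows = []
    for obs in STUDY_PRODUCT_IONS:
        theoretical = fragment_index[(obs.compound, obs.fragment_label, obs.series)]
        signed = ppm_error(obs.observed_mz, theoretical)
        rows.append(
            {
                "compound": obs.compound,
                "label": obs.fragment_label,
                "series": obs.series,
                "observed_mz": obs.observed_mz,
                "theoretical_mz": theoretical,
                "signed_ppm": signed,
                "recomputed_ppm": report_ppm(signed),
                "printed_ppm": obs.printed_ppm,
                "reliable": obs.reliable,
            }
        )
    return pd.DataFrame(rows)
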