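"""Matching observed MS/MS peaks to theoretical fragments.

Produces per-spectrum annotation ledgers in the style of a product-ion
assignment table (label, theoretical m/z, observed m/z, signed and
reported ppm error) and a variant explanation score used to rank candidate
structures against a spectrum — an automated surrogate for the manual
spectra curation step of a dereplication workflow.

Matching is one-to-one and greedy in order of increasing |ppm error|:
fragments are sparse on the m/z axis relative to the tolerance, so the
greedy assignment is effectively exact, and ppm (not Da) is the natural
error currency of high-resolution data. Intensity plays no role in
matching; it enters only the explained-intensity score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, NamedTuple, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import ppm_error, report_ppm
from .scaffold import AptVariant, TheoreticalFragment, generate_fragments

__all__ = [
    "Peak",
    "Spectrum",
    "FragmentAssignment",
    "AnnotationResult",
    "match_peaks",
    "annotate_variant",
    "rank_variants",
]

DEFAULT_TOL_PPM = 10.0


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass(frozen=True)
class Spectrum:
    """A centroided MS/MS spectrum: precursor plus a sorted peak list."""

    identifier: str
    precursor_mz: float
    peaks: Tuple[Peak, ...]
    precursor_charge: int = 1

    def __post_init__(self):
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        mzs = [p.mz for p in self.peaks]
        if any(m <= 0 for m in mzs):
            raise ValueError("peak m/z must be positive")
        if any(p.intensity < 0 for p in self.peaks):
            raise ValueError("peak intensity must be non-negative")
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("peaks must be sorted strictly ascending in m/z")

    @classmethod
    def from_arrays(
        cls,
        identifier: str,
        precursor_mz: float,
        mz: Sequence[float],
        intensity: Sequence[float],
        precursor_charge: int = 1,
    ) -> "Spectrum":
        """Build from parallel m/z / intensity arrays; peaks are sorted and
        exact m/z duplicates merged by intensity sum."""
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        peaks: List[Peak] = []
        for m, i in zip(mz, intensity):
            if peaks and peaks[-1].mz == m:
                peaks[-1] = Peak(m, peaks[-1].intensity + i)
            else:
                peaks.append(Peak(float(m), float(i)))
        return cls(identifier, float(precursor_mz), tuple(peaks), precursor_charge)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    @property
    def total_intensity(self) -> float:
        return float(sum(p.intensity for p in self.peaks))

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class FragmentAssignment:
    peak: Peak
    fragment: TheoreticalFragment
    signed_ppm: float

    @property
    def reported_ppm(self) -> float:
        return report_ppm(self.signed_ppm)


@dataclass
class AnnotationResult:
    """Annotation ledger for one (spectrum, variant) pair."""

    spectrum: Spectrum
    variant: AptVariant
    assignments: List[FragmentAssignment]
    unmatched_peaks: List[Peak]
    unmatched_fragments: List[TheoreticalFragment]
    tol_ppm: float = DEFAULT_TOL_PPM

    @property
    def n_assigned(self) -> int:
        return len(self.assignments)

    @property
    def explained_intensity_fraction(self) -> float:
        total = self.spectrum.total_intensity
        if total == 0:
            return 0.0
        return sum(a.peak.intensity for a in self.assignments) / total

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": a.fragment.label,
                "series": a.fragment.series,
                "theoretical_mz": a.fragment.mz,
                "observed_mz": a.peak.mz,
                "intensity": a.peak.intensity,
                "signed_ppm": a.signed_ppm,
                "reported_ppm": a.reported_ppm,
            }
            for a in sorted(self.assignments, key=lambda a: a.peak.mz)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "label",
                "series",
                "theoretical_mz",
                "observed_mz",
                "intensity",
                "signed_ppm",
                "reported_ppm",
            ],
        )


def match_peaks(
    spectrum: Spectrum,
    fragments: Sequence[TheoreticalFragment],
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> Tuple[List[FragmentAssignment], List[Peak], List[TheoreticalFragment]]:
    """One-to-one greedy assignment of peaks to fragments by smallest |ppm|.

    Returns (assignments, unmatched peaks, unmatched fragments). An empty
    fragment list simply leaves every peak unmatched.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    candidates = []
    for pi, peak in enumerate(spectrum.peaks):
        for fi, frag in enumerate(fragments):
            err = ppm_error(peak.mz, frag.mz)
            if abs(err) <= tol_ppm:
                candidates.append((abs(err), pi, fi, err))
    candidates.sort(key=lambda c: (c[0], c[1], fragments[c[2]].label))
    used_peaks: set = set()
    used_frags: set = set()
    assignments: List[FragmentAssignment] = []
    for _, pi, fi, err in candidates:
        if pi in used_peaks or fi in used_frags:
            continue
        used_peaks.add(pi)
        used_frags.add(fi)
        assignments.append(
            FragmentAssignment(
                peak=spectrum.peaks[pi], fragment=fragments[fi], signed_ppm=err
            )
        )
    unmatched_peaks = [p for i, p in enumerate(spectrum.peaks) if i not in used_peaks]
    unmatched_frags = [f for i, f in enumerate(fragments) if i not in used_frags]
    assignments.sort(key=lambda a: a.peak.mz)
    return assignments, unmatched_peaks, unmatched_frags


def annotate_variant(
    spectrum: Spectrum,
    variant: AptVariant,
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> AnnotationResult:
    """Annotate a spectrum against one candidate variant's fragments."""
    fragments = generate_fragments(variant)
    assignments, un_peaks, un_frags = match_peaks(spectrum, fragments, tol_ppm)
    return AnnotationResult(
        spectrum=spectrum,
        variant=variant,
        assignments=assignments,
        unmatched_peaks=un_peaks,
        unmatched_fragments=un_frags,
        tol_ppm=tol_ppm,
    )


def rank_variants(
    spectrum: Spectrum,
    candidates: Sequence[AptVariant],
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> List[Tuple[AptVariant, AnnotationResult]]:
    """Candidates ordered best-first by (assigned fragment count,
    explained intensity fraction), ties broken by variant name."""
    if not candidates:
        raise ValueError("at least one candidate variant is required")
    scored = [(v, annotate_variant(spectrum, v, tol_ppm)) for v in candidates]
    scored.sort(
        key=lambda vr: (
            -vr[1].n_assigned,
            -vr[1].explained_intensity_fraction,
            vr[0].name,
        )
    )
    return scored
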