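"""GNPS-style molecular networking on centroided MS/MS spectra.

The pipeline mirrors the classic molecular-networking recipe: spectra are
precursor- and window-filtered, clustered into consensus spectra by parent
mass, compared pairwise with the modified cosine score (fragment matches
may be offset by the precursor mass difference, which is what lets CH2
homologs of a cyclic peptide land in one cluster), and assembled into a
graph whose edges must pass a cosine and matched-peak threshold and a
mutual top-K rank filter. A library search with analog mass shifts uses
the same score.

Default parameters: precursor exclusion ±17 Da; top 6 peaks per ±50 Da
window; fragment tolerance 0.025 Da; parent mass tolerance 0.1 Da; cosine
> 0.65 with more than four matched peaks for network edges; mutual top-10
rank; library score > 0.7 with at least four matched peaks and a maximum
analog shift of 200 Da; consensus spectra with fewer than 2 members
discarded.

The consensus step is a deliberately simple stand-in for MS-Cluster:
single-linkage grouping in precursor space gated by the modified-cosine
threshold, with tolerance-merged peak lists. Peak matching inside the
modified cosine is greedy by descending intensity product; tests verify it
against an exhaustive maximum-matching oracle on small spectra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .annotation import Peak, Spectrum

__all__ = [
    "NetworkParams",
    "ConsensusSpectrum",
    "SpectralGraph",
    "LibraryMatch",
    "filter_spectrum",
    "modified_cosine",
    "consensus_cluster",
    "build_network",
    "library_match",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkParams:
    """All tunables of the networking stage (see module docstring)."""

    precursor_exclusion_da: float = 17.0
    window_da: float = 50.0
    peaks_per_window: int = 6
    fragment_tol_da: float = 0.025
    parent_mass_tol_da: float = 0.1
    min_cosine: float = 0.65
    # network edges need strictly more than four matched peaks (>= 5);
    # library matches need at least four (>= 4)
    min_matched_peaks: int = 5
    mutual_rank_k: int = 10
    library_min_score: float = 0.7
    library_min_matched_peaks: int = 4
    max_analog_shift_da: float = 200.0
    min_cluster_size: int = 2

    def __post_init__(self):
        for name in (
            "precursor_exclusion_da",
            "window_da",
            "fragment_tol_da",
            "parent_mass_tol_da",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("min_cosine", "library_min_score"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mutual_rank_k < 1:
            raise ValueError("mutual_rank_k must be >= 1")


@dataclass(frozen=True)
class ConsensusSpectrum(Spectrum):
    """A merged representative of one or more clustered spectra."""

    member_ids: Tuple[str, ...] = ()

    @property
    def member_count(self) -> int:
        return max(1, len(self.member_ids))


@dataclass
class SpectralGraph:
    """Nodes are consensus spectra; edges carry similarity evidence."""

    graph: nx.Graph
    spectra: Dict[str, Spectrum] = field(default_factory=dict)

    @property
    def components(self) -> List[List[str]]:
        comps = [sorted(c) for c in nx.connected_components(self.graph)]
        return sorted((c for c in comps if len(c) > 1), key=lambda c: (-len(c), c))

    @property
    def singletons(self) -> List[str]:
        return sorted(n for n in self.graph if self.graph.degree(n) == 0)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "cosine": d["cosine"],
                "matched_peaks": d["matched_peaks"],
                "delta_mz": d["delta_mz"],
            }
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(
            rows, columns=["source", "target", "cosine", "matched_peaks", "delta_mz"]
        )

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


@dataclass(frozen=True)
class LibraryMatch:
    query_id: str
    library_id: str
    score: float
    matched_peaks: int
    precursor_shift: float


def filter_spectrum(spectrum: Spectrum, params: NetworkParams | None = None) -> Spectrum:
    """Precursor-exclusion then window filter.

    Peaks within the precursor exclusion half-width of the precursor m/z
    are removed; a remaining peak survives iff it ranks among the top
    ``peaks_per_window`` intensities within its own ±``window_da`` window.
    Intensity ties rank the lower-m/z peak first, so the result is
    deterministic. Peak order is preserved.
    """
    params = params or NetworkParams()
    kept = [
        p
        for p in spectrum.peaks
        if abs(p.mz - spectrum.precursor_mz) > params.precursor_exclusion_da
    ]
    surviving = []
    for p in kept:
        better = sum(
            1
            for q in kept
            if abs(q.mz - p.mz) <= params.window_da
            and (q.intensity > p.intensity or (q.intensity == p.intensity and q.mz < p.mz))
        )
        if better < params.peaks_per_window:
            surviving.append(p)
    return replace(spectrum, peaks=tuple(surviving))


def _normalized_sqrt_intensities(spectrum: Spectrum) -> np.ndarray:
    vec = np.sqrt(spectrum.intensity_array)
    norm = np.linalg.norm(vec)
    return vec / norm if norm > 0 else vec


def modified_cosine(
    a: Spectrum, b: Spectrum, params: NetworkParams | None = None
) -> Tuple[float, int]:
    """Modified cosine score and matched-peak count between two spectra.

    Two peaks may match directly (|Δm/z| ≤ fragment tolerance) or shifted
    by the precursor mass difference. Intensities are square-root
    transformed and each spectrum normalized to unit length; the score is
    the sum of intensity products over a greedy one-to-one matching taken
    in order of descending product. Bounded in [0, 1] (up to rounding) and
    symmetric.
    """
    params = params or NetworkParams()
    if len(a) == 0 or len(b) == 0:
        return 0.0, 0
    mza, mzb = a.mz_array, b.mz_array
    na, nb = _normalized_sqrt_intensities(a), _normalized_sqrt_intensities(b)
    shift = a.precursor_mz - b.precursor_mz
    diff = mza[:, None] - mzb[None, :]
    allowed = (np.abs(diff) <= params.fragment_tol_da) | (
        np.abs(diff - shift) <= params.fragment_tol_da
    )
    ii, jj = np.nonzero(allowed)
    if ii.size == 0:
        return 0.0, 0
    products = na[ii] * nb[jj]
    order = np.lexsort((jj, ii, -products))
    used_a: set = set()
    used_b: set = set()
    score = 0.0
    matched = 0
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += float(products[k])
        matched += 1
    return min(score, 1.0), matched


def _merge_peaks(peaks: Sequence[Peak], tol: float) -> Tuple[Peak, ...]:
    """Single-linkage merge of peaks within ``tol`` Da; merged m/z is the
    intensity-weighted mean, intensity the sum."""
    if not peaks:
        return ()
    peaks = sorted(peaks, key=lambda p: p.mz)
    groups: List[List[Peak]] = [[peaks[0]]]
    for p in peaks[1:]:
        if p.mz - groups[-1][-1].mz <= tol:
            groups[-1].append(p)
        else:
            groups.append([p])
    merged = []
    for group in groups:
        total = sum(p.intensity for p in group)
        if total > 0:
            mz = sum(p.mz * p.intensity for p in group) / total
        else:
            mz = sum(p.mz for p in group) / len(group)
        merged.append(Peak(mz, total))
    return tuple(merged)


def consensus_cluster(
    spectra: Sequence[Spectrum], params: NetworkParams | None = None
) -> List[ConsensusSpectrum]:
    """Group spectra by precursor mass and similarity; merge each group.

    Single-linkage: two spectra join a cluster if their precursors agree
    within the parent mass tolerance and their modified cosine clears the
    network threshold. Consensus precursor is the member mean; the peak
    list is tolerance-merged. Clusters smaller than ``min_cluster_size``
    are discarded (set it to 1 to keep lone spectra).
    """
    params = params or NetworkParams()
    g = nx.Graph()
    g.add_nodes_from(range(len(spectra)))
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            if (
                abs(spectra[i].precursor_mz - spectra[j].precursor_mz)
                <= params.parent_mass_tol_da
            ):
                score, _ = modified_cosine(spectra[i], spectra[j], params)
                if score > params.min_cosine:
                    g.add_edge(i, j)
    out: List[ConsensusSpectrum] = []
    for component in nx.connected_components(g):
        members = sorted(component, key=lambda i: spectra[i].identifier)
        if len(members) < params.min_cluster_size:
            continue
        member_spectra = [spectra[i] for i in members]
        all_peaks = [p for s in member_spectra for p in s.peaks]
        out.append(
            ConsensusSpectrum(
                identifier=member_spectra[0].identifier,
                precursor_mz=float(
                    np.mean([s.precursor_mz for s in member_spectra])
                ),
                peaks=_merge_peaks(all_peaks, params.fragment_tol_da),
                precursor_charge=member_spectra[0].precursor_charge,
                member_ids=tuple(s.identifier for s in member_spectra),
            )
        )
    out.sort(key=lambda c: c.identifier)
    logger.info("consensus clustering: %d spectra -> %d consensus", len(spectra), len(out))
    return out


def build_network(
    consensus: Sequence[Spectrum], params: NetworkParams | None = None
) -> SpectralGraph:
    """Similarity graph over consensus spectra.

    Candidate edges must have cosine above ``min_cosine`` and at least
    ``min_matched_peaks`` matched peaks; an edge then survives iff each
    endpoint ranks within the other's top ``mutual_rank_k`` most similar
    candidate neighbors (ties broken by higher cosine, then lower node
    id).
    """
    params = params or NetworkParams()
    if not consensus:
        raise ValueError("consensus spectrum list is empty")
    g = nx.Graph()
    for s in consensus:
        member_count = s.member_count if isinstance(s, ConsensusSpectrum) else 1
        g.add_node(s.identifier, precursor_mz=s.precursor_mz, member_count=member_count)
    candidates: Dict[str, List[Tuple[float, str]]] = {s.identifier: [] for s in consensus}
    edge_data = {}
    for i in range(len(consensus)):
        for j in range(i + 1, len(consensus)):
            a, b = consensus[i], consensus[j]
            score, matched = modified_cosine(a, b, params)
            if score > params.min_cosine and matched >= params.min_matched_peaks:
                candidates[a.identifier].append((score, b.identifier))
                candidates[b.identifier].append((score, a.identifier))
                edge_data[frozenset((a.identifier, b.identifier))] = (score, matched)
    top: Dict[str, set] = {}
    for node, neigh in candidates.items():
        neigh.sort(key=lambda sc: (-sc[0], sc[1]))
        top[node] = {other for _, other in neigh[: params.mutual_rank_k]}
    prec = {s.identifier: s.precursor_mz for s in consensus}
    for key, (score, matched) in edge_data.items():
        u, v = sorted(key)
        if v in top[u] and u in top[v]:
            g.add_edge(
                u,
                v,
                cosine=score,
                matched_peaks=matched,
                delta_mz=round(abs(prec[u] - prec[v]), 2),
            )
    logger.info(
        "network: %d nodes, %d edges (%d candidate pairs before mutual rank)",
        g.number_of_nodes(),
        g.number_of_edges(),
        len(edge_data),
    )
    return SpectralGraph(graph=g, spectra={s.identifier: s for s in consensus})


def library_match(
    query: Spectrum,
    library: Sequence[Spectrum],
    params: NetworkParams | None = None,
) -> List[LibraryMatch]:
    """Analog-aware library search with the modified cosine score.

    Library spectra are assumed filtered in the same manner as the query.
    Matches require score above ``library_min_score``, at least
    ``library_min_matched_peaks`` matched peaks, and a precursor shift of
    at most ``max_analog_shift_da``.
    """
    params = params or NetworkParams()
    matches = []
    for entry in library:
        shift = query.precursor_mz - entry.precursor_mz
        if abs(shift) > params.max_analog_shift_da:
            continue
        score, matched = modified_cosine(query, entry, params)
        if score > params.library_min_score and matched >= params.library_min_matched_peaks:
            matches.append(
                LibraryMatch(
                    query_id=query.identifier,
                    library_id=entry.identifier,
                    score=score,
                    matched_peaks=matched,
                    precursor_shift=shift,
                )
            )
    matches.sort(key=lambda m: (-m.score, m.library_id))
    return matches
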