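"""Spectral filtering, modified cosine, clustering and graph construction.

The greedy peak matching inside the modified cosine is verified against an
exact dynamic-programming oracle (maximum-weight one-to-one matching over
bitmasks), and against matchms' independent ModifiedCosine implementation.
"""

import numpy as np
import pytest

from aptnet import (
    NetworkParams,
    SimulationConfig,
    Spectrum,
    build_network,
    consensus_cluster,
    filter_spectrum,
    library_match,
    modified_cosine,
    simulate_collection,
    simulate_spectrum,
)

from conftest import random_spectrum


def _spectrum(mzs, intensities, precursor, identifier="s"):
    return Spectrum.from_arrays(identifier, precursor, mzs, intensities)


# ---------------------------------------------------------------- filtering


def test_filter_removes_peaks_near_precursor():
    s = _spectrum([385.22, 790.00], [10.0, 10.0], precursor=803.44)
    out = filter_spectrum(s)
    assert [p.mz for p in out.peaks] == [385.22]


def test_filter_keeps_small_spectrum_unchanged():
    s = _spectrum([100.0, 110.0, 120.0, 130.0, 140.0, 149.0], [1, 2, 3, 4, 5, 6],
                  precursor=800.0)
    out = filter_spectrum(s)
    assert out.peaks == s.peaks


def _window_filter_oracle(spectrum, params):
    kept = [
        p
        for p in spectrum.peaks
        if abs(p.mz - spectrum.precursor_mz) > params.precursor_exclusion_da
    ]
    survivors = []
    for p in kept:
        window = [q for q in kept if abs(q.mz - p.mz) <= params.window_da]
        window.sort(key=lambda q: (-q.intensity, q.mz))
        if p in window[: params.peaks_per_window]:
            survivors.append(p)
    return tuple(survivors)


def test_window_filter_agrees_with_oracle_on_random_spectra(rng):
    params = NetworkParams()
    for _ in range(100):
        s = random_spectrum(rng, n_peaks=int(rng.integers(5, 60)))
        assert filter_spectrum(s, params).peaks == _window_filter_oracle(s, params)


# ------------------------------------------------------------ modified cosine


def _exhaustive_score(a, b, params):
    """Exact maximum-weight one-to-one matching via bitmask DP."""
    mza, mzb = a.mz_array, b.mz_array
    ia = np.sqrt(a.intensity_array)
    ib = np.sqrt(b.intensity_array)
    na = ia / np.linalg.norm(ia) if np.linalg.norm(ia) else ia
    nb = ib / np.linalg.norm(ib) if np.linalg.norm(ib) else ib
    shift = a.precursor_mz - b.precursor_mz
    allowed = {}
    for i, ma in enumerate(mza):
        for j, mb in enumerate(mzb):
            if abs(ma - mb) <= params.fragment_tol_da or abs(
                ma - mb - shift
            ) <= params.fragment_tol_da:
                allowed.setdefault(i, []).append(j)
    dp = {0: 0.0}
    for i in range(len(mza)):
        new = dict(dp)
        for mask, val in dp.items():
            for j in allowed.get(i, []):
                bit = 1 << j
                if not mask & bit:
                    cand = val + na[i] * nb[j]
                    key = mask | bit
                    if cand > new.get(key, -1.0):
                        new[key] = cand
        dp = new
    return max(dp.values())


def test_identical_spectra_score_one(rng):
    for _ in range(20):
        s = random_spectrum(rng, n_peaks=12)
        score, matched = modified_cosine(s, s)
        assert score == pytest.approx(1.0, abs=1e-9)
        assert matched == len(s)


def test_disjoint_spectra_score_zero():
    a = _spectrum([100.0, 200.0], [1.0, 1.0], precursor=500.0)
    b = _spectrum([150.0, 250.0], [1.0, 1.0], precursor=501.0)
    score, matched = modified_cosine(a, b)
    assert (score, matched) == (0.0, 0)


def test_empty_spectrum_scores_zero():
    a = Spectrum("a", 500.0, ())
    b = _spectrum([150.0], [1.0], precursor=500.0)
    assert modified_cosine(a, b) == (0.0, 0)


def test_shifted_analog_matches_through_precursor_offset():
    # five peaks; two move with the precursor by +14.0157 (CH2 homolog)
    mz = np.array([120.0, 230.0, 340.0, 450.0, 560.0])
    inten = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
    a = _spectrum(mz, inten, precursor=700.0, identifier="a")
    b = _spectrum(
        np.concatenate([mz[:3], mz[3:] + 14.0157]),
        inten,
        precursor=714.0157,
        identifier="b",
    )
    params = NetworkParams()
    score, matched = modified_cosine(a, b, params)
    assert matched == 5
    assert score == pytest.approx(1.0, abs=1e-9)
    assert score == pytest.approx(_exhaustive_score(a, b, params), abs=1e-9)


def test_greedy_matching_equals_exhaustive_oracle(rng):
    params = NetworkParams()
    for _ in range(60):
        n_a, n_b = rng.integers(1, 9), rng.integers(1, 9)
        # peak densities of real centroided spectra: collisions between
        # tolerance windows happen but are sparse
        a = random_spectrum(rng, n_peaks=int(n_a), mz_range=(100.0, 120.0), identifier="a")
        b = random_spectrum(rng, n_peaks=int(n_b), mz_range=(100.0, 120.0), identifier="b")
        score, _ = modified_cosine(a, b, params)
        assert score == pytest.approx(_exhaustive_score(a, b, params), abs=1e-9)


def test_symmetry_and_bounds(rng):
    params = NetworkParams()
    for _ in range(50):
        a = random_spectrum(rng, identifier="a")
        b = random_spectrum(rng, identifier="b")
        sab, mab = modified_cosine(a, b, params)
        sba, mba = modified_cosine(b, a, params)
        assert sab == pytest.approx(sba, abs=1e-9)
        assert mab == mba
        assert 0.0 <= sab <= 1.0


def test_against_matchms_reference(rng):
    """Cross-check against matchms' ModifiedCosine (which does not
    square-root-transform, so it receives sqrt intensities)."""
    matchms = pytest.importorskip("matchms")
    from matchms.similarity import ModifiedCosine

    params = NetworkParams()
    reference = ModifiedCosine(tolerance=params.fragment_tol_da)
    for _ in range(25):
        a = random_spectrum(rng, n_peaks=15, identifier="a")
        b = random_spectrum(rng, n_peaks=15, identifier="b")
        score, matched = modified_cosine(a, b, params)
        ma = matchms.Spectrum(
            mz=a.mz_array,
            intensities=np.sqrt(a.intensity_array),
            metadata={"precursor_mz": a.precursor_mz},
            metadata_harmonization=False,
        )
        mb = matchms.Spectrum(
            mz=b.mz_array,
            intensities=np.sqrt(b.intensity_array),
            metadata={"precursor_mz": b.precursor_mz},
            metadata_harmonization=False,
        )
        res = reference.pair(ma, mb)
        assert score == pytest.approx(float(res["score"]), abs=1e-6)
        assert matched == int(res["matches"])


# ------------------------------------------------------------------ consensus


def test_replicates_collapse_to_one_consensus(apt802):
    cfg = SimulationConfig(seed=5, n_noise_peaks=0, fragment_dropout=0.0)
    rng = np.random.default_rng(5)
    spectra = [
        simulate_spectrum(apt802, cfg, rng, identifier=f"rep{i}") for i in range(3)
    ]
    consensus = consensus_cluster(spectra)
    assert len(consensus) == 1
    assert consensus[0].member_count == 3
    expected = np.mean([s.precursor_mz for s in spectra])
    assert consensus[0].precursor_mz == pytest.approx(expected, abs=1e-9)


def test_lone_spectrum_discarded_by_default(rng):
    s = random_spectrum(rng)
    assert consensus_cluster([s]) == []


def test_lone_spectrum_kept_when_discard_disabled(rng):
    s = random_spectrum(rng)
    out = consensus_cluster([s], NetworkParams(min_cluster_size=1))
    assert len(out) == 1
    assert out[0].member_count == 1


# -------------------------------------------------------------------- network


def test_two_identical_spectra_form_one_edge(rng):
    s = random_spectrum(rng, n_peaks=10, identifier="a")
    t = Spectrum("b", s.precursor_mz, s.peaks)
    graph = build_network([s, t], NetworkParams(min_cluster_size=1))
    assert graph.graph.number_of_edges() == 1
    data = graph.graph.edges["a", "b"]
    assert data["cosine"] == pytest.approx(1.0, abs=1e-9)
    assert data["matched_peaks"] == 10
    assert data["delta_mz"] == 0.0


def test_dissimilar_spectra_stay_singletons(rng):
    spectra = [random_spectrum(rng, n_peaks=8, identifier=f"s{i}") for i in range(6)]
    graph = build_network(spectra)
    assert graph.graph.number_of_edges() == 0
    assert len(graph.singletons) == 6
    assert graph.components == []


def _family_collection(seed):
    cfg = SimulationConfig(seed=seed, replicates_per_compound=1, n_background=20)
    spectra, truth = simulate_collection(cfg)
    return spectra, truth


def test_analog_family_forms_clean_component():
    spectra, truth = _family_collection(seed=42)
    params = NetworkParams(min_cluster_size=1)
    filtered = [filter_spectrum(s, params) for s in spectra]
    graph = build_network(filtered, params)
    family = set(truth.loc[truth.label != "background", "spectrum_id"])
    comps = [set(c) for c in graph.components]
    assert family in comps
    edges = graph.edge_table()
    family_edges = edges[edges.source.isin(family) & edges.target.isin(family)]
    # edge spacings are CH2 multiples (14.016 / 28.031 Da) up to mass noise
    for dm in family_edges.delta_mz:
        assert min(abs(dm - 14.016), abs(dm - 28.031)) < 0.03


def test_mutual_rank_pruning_is_contractive(rng):
    base = random_spectrum(rng, n_peaks=12, identifier="base")
    spectra = [base]
    for i in range(8):
        jitter = rng.normal(0, 0.002, size=len(base))
        mz = base.mz_array + jitter
        inten = base.intensity_array * rng.uniform(0.5, 1.5, size=len(base))
        spectra.append(
            Spectrum.from_arrays(f"v{i}", base.precursor_mz + i * 0.5, mz, inten)
        )
    def edges(params):
        return set(map(frozenset, build_network(spectra, params).graph.edges()))

    e_k1 = edges(NetworkParams(mutual_rank_k=1, min_cluster_size=1))
    e_k3 = edges(NetworkParams(mutual_rank_k=3, min_cluster_size=1))
    e_k10 = edges(NetworkParams(mutual_rank_k=10, min_cluster_size=1))
    assert e_k1 <= e_k3 <= e_k10
    e_high = edges(NetworkParams(min_cosine=0.9, min_cluster_size=1))
    assert e_high <= e_k10


# ------------------------------------------------------------- library search


def test_library_self_match(rng):
    s = random_spectrum(rng, n_peaks=10, identifier="q")
    matches = library_match(s, [s])
    assert len(matches) == 1
    assert matches[0].score == pytest.approx(1.0, abs=1e-9)


def test_library_analog_match(apt788, apt802):
    cfg = SimulationConfig(seed=9, ppm_sigma=0.0, fragment_dropout=0.0, n_noise_peaks=0)
    query = simulate_spectrum(apt802, cfg, identifier="query")
    entry = simulate_spectrum(apt788, cfg, identifier="lib788")
    matches = library_match(query, [entry])
    assert len(matches) == 1
    assert matches[0].precursor_shift == pytest.approx(14.0157, abs=1e-3)


def test_library_match_respects_max_shift(rng):
    q = random_spectrum(rng, n_peaks=10, identifier="q")
    far = Spectrum("far", q.precursor_mz + 250.0, q.peaks)
    assert library_match(q, [far]) == []
    assert library_match(q, []) == []
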