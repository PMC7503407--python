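# Methods

## Mass scale

All masses are computed from a hard-coded table of IUPAC/CODATA
monoisotopic atomic masses (C = 12 exactly, H = 1.00782503207,
N = 14.0030740048, O = 15.9949146196), so results do not depend on any
external library version. Ion m/z uses the *electron-corrected*
protonation convention: `[M+H]+` is the neutral mass plus the proton
mass 1.00727646 Da (mass of H minus one electron), not plus the mass of
a hydrogen atom. The choice is empirical as well as physical: the
published product-ion errors at m/z ≥ 385 agree with the
electron-corrected convention to ≤ 0.15 ppm after one-decimal rounding,
while the atom-mass convention drifts by ~0.7 ppm at 803. Immonium-type
cations are computed as the cation formula mass minus one electron,
which is the identical convention stated differently. Reported ppm
errors are unsigned and rounded half-up to one decimal, matching the
usual tabulation style.

## Scaffold model and fragment rules

The anabaenopeptin scaffold is a 5-residue ring (Lys–X3–X4–X5–X6,
closed between the C-terminal carboxyl and the Lys α-amine) with an
exocyclic residue X1 attached to the Lys side through a ureido N–CO–N
bond. Two equivalent derivations give the neutral formula — Σ(six
residue formulas) + CO2, or cyclic pentapeptide + free exocyclic amino
acid + CO − 2H — and the test suite asserts their identity.

Three product-ion series are generated, all singly protonated
(multiply charged fragments are not modeled; the observed ions of this
compound class are singly charged):

* **ring_b**: every contiguous run of the ring path X3–X4–X5–X6 (the
  ring opened at Lys, losing the ureido part); composition = Σ(run
  residues) + proton. Both traversal directions give the same residue
  sets, so runs of the linear path are exhaustive.
* **ureido_series**: every arc of the 5-ring that contains Lys, with
  the exocyclic X1 optionally retained; composition = Σ(residues) + CO2
  + proton. A single rule therefore covers the `CO-Lys-Phe-MeAla`-type
  ions, their X1-extended forms, and the Trp-loss ions
  `X1-CO-Lys-(X3)-(Phe-MeAla)` (the length-4 arc that skips X4). The
  composition rule was chosen because it reproduces the full set of
  published ureido-ion masses (405/504/518/603/617/631); assignment
  labels in the literature name only residues, never compositions.
* **immonium**: residue-diagnostic cations carried by the block
  library (Lys → C5H10N+, Trp → C9H8N+, MeAla+CO → C5H8NO2+).

A brute-force oracle that enumerates all connected residue subsets of
the 6-node molecule graph (ring + pendant X1) confirms the enumeration
is complete and duplicate-free. Stereochemistry (the D-Lys installed by
the epimerization domain) is annotation only; mass arithmetic is
stereochemistry-blind. Ile and Leu are carried both as individual
blocks and as a merged `Ile/Leu` mass class, since conventional MS
cannot distinguish them; enumeration merges them by default.

## Annotation and variant ranking

Peak/fragment matching is one-to-one and greedy in order of increasing
|ppm error|. Because theoretical fragments are separated by far more
than the tolerance window, greedy assignment is effectively exact; a
maximum-bipartite-matching oracle in the tests confirms agreement on
noise spectra. The default tolerance is 10 ppm — more than double the
largest reliable published assignment error (≈ 4 ppm) yet narrow enough
that random noise peaks rarely match (the expected number of 10 ppm
coincidences for a uniform noise peak against 35 fragments is ≪ 1).
Matching ignores intensity; intensity enters only the explanation score
(assigned-fragment count first, explained intensity fraction second,
name as deterministic tie-break). This ranking reproduces the
published structure-elucidation logic: candidates sharing a precursor
mass (Val@X1/Xle@X3 vs Xle@X1/Val@X3) are separated by the
X1-containing ureido ions (504.28 vs 518.30) and the X3-containing ring
ions (385.22 vs 371.21).

## Published-value checks

`aptnet.reference` carries the published observed m/z and printed
one-decimal ppm errors for the 27 assigned product ions of the three
compounds. Fourteen rows are used as exact checks (recomputed |ppm|
within 0.15 of the printed value — the slack that 4-decimal printing of
the observed m/z allows). Thirteen rows are flagged unreliable and are
annotated but not asserted: the nine low-m/z diagnostic ions print
different errors for identical observed values across compounds; the
272.196 entry is inconsistent with its own error column by three orders
of magnitude; and the printed errors at 272.1394, 518.2973 and 617.3677
cannot be produced by any standard mass-scale convention given the
printed precision (e.g. 518.2973 prints 3.0 ppm while the residue-sum
theoretical value is 518.29731, i.e. 0.0 ppm).

## Molecular networking

The networking stage follows the classic GNPS recipe with its standard
parameters: peaks within ±17 Da of the precursor removed; window filter
keeping the six most intense peaks per ±50 Da window (intensity ties
rank the lower m/z first, making the filter deterministic); consensus
clustering at 0.1 Da parent tolerance; modified cosine with 0.025 Da
fragment tolerance; edges require cosine above 0.65 and strictly more
than four matched peaks (≥ 5), while library matches require score
above 0.7 and at least four (≥ 4) — the two phrasings are implemented
literally and both are configurable; mutual top-10 rank pruning; analog
library search up to a 200 Da precursor shift.

The modified cosine square-root-transforms intensities and normalizes
each spectrum to unit length; peaks match directly or offset by the
precursor mass difference; the score sums intensity products over a
greedy one-to-one matching taken in descending product order. The
greedy choice is standard practice; an exact bitmask-DP
maximum-matching oracle verifies it on all tested small spectra, and
matchms' independent implementation serves as a cross-check. In
pathologically dense spectra (many peaks within one tolerance window)
greedy can fall below the exhaustive optimum; centroided
high-resolution spectra do not occupy that regime.

Consensus building is a deliberately simple stand-in for MS-Cluster,
whose exact heuristics are not public in algorithmic detail:
single-linkage grouping by precursor (0.1 Da) gated by the network
cosine threshold, peak lists merged at the fragment tolerance with
intensity-weighted m/z, precursor = member mean, clusters below the
minimum size (default 2) discarded. The ±17 Da precursor exclusion is
applied as a single symmetric window around the precursor only (not
around isotopologues). Edge Δm is reported as the absolute precursor
difference rounded to two decimals.

## Synthetic data

The simulator generates what the analysis assumes about real data and
no more. Fragment m/z values receive Gaussian *relative* noise with
sigma 2 ppm — chosen so that ~95% of absolute errors fall below 4 ppm,
the spread of the published assignment table. Each fragment is dropped
with probability 0.1 (real spectra rarely show every theoretically
possible cleavage). Intensities are log-normal with the base intensity
keyed deterministically to the fragment label: the relative abundance
of a product ion is governed by fragmentation energetics and is
reproducible across replicates and largely conserved across close
analogs, which is exactly the correlation structure that makes
replicate clustering and analog networking work; per-spectrum
multiplicative jitter (sigma 0.3 on the log scale) models run-to-run
variation. Ten uniform background noise peaks per spectrum sit two
log-units below the fragment intensity scale, as instrument noise does.
Background spectra draw their peak counts from the empirical compound
peak-count distribution so networking specificity cannot be won on peak
count alone, but their peaks are uniform and structureless.

What the simulator does **not** model — isotope envelopes, charge
states > 1, chimeric spectra, retention time, intensity saturation,
correlated chemical noise — bounds what passing tests show: recovery
rates measured here demonstrate the correctness and calibration of the
pipeline under its stated assumptions, not its performance on raw
vendor data, where peak-picking quality dominates. Correspondingly, the
published real-data network (30 clusters, 108 singletons) is not a
target: it depends on the deposited raw data and vendor centroiding.

## Problem sizes and determinism

The acceptance surface uses 50 seeded collections (one spectrum per
analog plus 20 background spectra, 2 ppm noise) for the
planted-family recovery and variant-ranking rates, 200 replicates for
the fragment-recovery calibration, and 500 for the ppm-noise
calibration — sizes at which the binomial standard error is well below
the asserted margins. All randomness flows from single integer seeds
through `numpy.random.Generator`, so every figure in the README and
every test is bit-reproducible.
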