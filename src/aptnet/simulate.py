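"""Simulated anabaenopeptin product-ion spectra and spectrum collections.

The generator emulates what a high-resolution Q-TOF sees for protonated
anabaenopeptins: every theoretical fragment of a variant, each m/z
perturbed by Gaussian relative error (sigma 2 ppm by default, matching an
instrument whose assignment errors span roughly 0-4 ppm), a fraction of
fragments dropped (default 10%), plus weak uniform background noise
peaks.

Fragment intensities follow a log-normal model in which the base
intensity is a reproducible property of the fragment itself (keyed
deterministically by the fragment label), modulated by per-spectrum
multiplicative noise. This mirrors real CID behavior: the relative
abundance of a product ion is governed by fragmentation energetics and is
highly reproducible across replicate spectra and largely conserved across
close structural analogs — which is precisely what makes replicate
clustering and analog networking work on real data. No absolute intensity
scale is meaningful; only rank and ratio behavior is asserted downstream.

Background spectra carry the same peak-count statistics as compound
spectra but no shared fragment structure, so networking specificity is
tested on spectral content rather than on peak-count artifacts.

Everything is driven by a single integer seed; identical config and seed
give identical output on any platform.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .annotation import Spectrum
from .chem import monoisotopic_mass, protonated_mz
from .scaffold import AptVariant, assemble_neutral_formula, generate_fragments, make_variant

__all__ = [
    "SimulationConfig",
    "study_family",
    "simulate_spectrum",
    "simulate_collection",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the spectrum simulator (see module docstring)."""

    seed: int = 0
    ppm_sigma: float = 2.0
    intensity_log_mean: float = 7.0  # ln of arbitrary intensity units
    intensity_log_sigma: float = 1.0
    replicate_log_sigma: float = 0.3  # per-spectrum multiplicative jitter
    n_noise_peaks: int = 10
    noise_mz_range: Tuple[float, float] = (100.0, 1000.0)
    noise_log_mean: float = 5.0  # noise peaks are weak relative to fragments
    fragment_dropout: float = 0.1
    replicates_per_compound: int = 3
    n_background: int = 20

    def __post_init__(self):
        if self.ppm_sigma < 0:
            raise ValueError("ppm_sigma must be non-negative")
        if not 0.0 <= self.fragment_dropout < 1.0:
            raise ValueError("fragment_dropout must lie in [0, 1)")
        if self.noise_mz_range[0] >= self.noise_mz_range[1]:
            raise ValueError("noise_mz_range must be increasing")


def study_family() -> Dict[str, AptVariant]:
    """The three Trp-containing compounds: anabaenopeptin 788 (Val at X1
    and X3), 802 (Val at X1, Ile/Leu at X3) and 816 (Ile/Leu at both)."""
    return {
        "APT788": make_variant(["Val", "Lys", "Val", "Trp", "MeAla", "Phe"]),
        "APT802": make_variant(["Val", "Lys", "Ile/Leu", "Trp", "MeAla", "Phe"]),
        "APT816": make_variant(["Ile/Leu", "Lys", "Ile/Leu", "Trp", "MeAla", "Phe"]),
    }


def _perturb(mz: float, config: SimulationConfig, rng: np.random.Generator) -> float:
    return mz * (1.0 + rng.normal(0.0, config.ppm_sigma) * 1e-6)


def _base_intensity(label: str, config: SimulationConfig) -> float:
    """Reproducible fragment base intensity, keyed by the fragment label
    so replicates — and shared fragments of analogs — agree."""
    key_rng = np.random.default_rng([config.seed, zlib.crc32(label.encode())])
    return float(
        np.exp(key_rng.normal(config.intensity_log_mean, config.intensity_log_sigma))
    )


def simulate_spectrum(
    variant: AptVariant,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    identifier: str = "sim",
) -> Spectrum:
    """One simulated product-ion spectrum of a variant.

    Fragment peaks at theoretical m/z perturbed by ppm noise, retained
    with probability 1 - dropout, intensity = fragment base intensity
    times per-spectrum log-normal jitter, plus weak uniform noise peaks;
    precursor is the perturbed [M+H]+.
    """
    config = config or SimulationConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    fragments = generate_fragments(variant)
    mzs: List[float] = []
    intensities: List[float] = []
    for frag in fragments:
        if rng.random() < config.fragment_dropout:
            continue
        mzs.append(_perturb(frag.mz, config, rng))
        intensities.append(
            _base_intensity(frag.label, config)
            * float(np.exp(rng.normal(0.0, config.replicate_log_sigma)))
        )
    noise_mz = rng.uniform(*config.noise_mz_range, size=config.n_noise_peaks)
    noise_intensity = np.exp(
        rng.normal(config.noise_log_mean, config.intensity_log_sigma, size=config.n_noise_peaks)
    )
    all_mz = np.concatenate([mzs, noise_mz])
    all_intensity = np.concatenate([intensities, noise_intensity])
    precursor = _perturb(
        protonated_mz(monoisotopic_mass(assemble_neutral_formula(variant))),
        config,
        rng,
    )
    return Spectrum.from_arrays(identifier, precursor, all_mz, all_intensity)


def _background_spectrum(
    n_peaks: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    identifier: str,
) -> Spectrum:
    lo, hi = config.noise_mz_range
    mz = rng.uniform(lo, hi, size=n_peaks)
    intensities = np.exp(
        rng.normal(config.intensity_log_mean, config.intensity_log_sigma, size=n_peaks)
    )
    precursor = rng.uniform(max(lo, 300.0), hi)
    return Spectrum.from_arrays(identifier, precursor, mz, intensities)


def simulate_collection(
    config: SimulationConfig | None = None,
    variants: Dict[str, AptVariant] | None = None,
) -> Tuple[List[Spectrum], pd.DataFrame]:
    """Replicate spectra of the study family plus background spectra.

    Returns the spectra and a ground-truth table (spectrum id, label,
    generating variant name or ``background``). Background peak counts
    are drawn from the empirical counts of the compound spectra.
    """
    config = config or SimulationConfig()
    variants = variants if variants is not None else study_family()
    rng = np.random.default_rng(config.seed)
    spectra: List[Spectrum] = []
    truth_rows = []
    for label, variant in variants.items():
        for rep in range(config.replicates_per_compound):
            sid = f"{label}_r{rep}"
            s = simulate_spectrum(variant, config, rng, identifier=sid)
            spectra.append(s)
            truth_rows.append(
                {"spectrum_id": sid, "label": label, "variant": variant.name}
            )
    compound_counts = [len(s) for s in spectra] or [30]
    for k in range(config.n_background):
        sid = f"bg_{k}"
        n_peaks = int(rng.choice(compound_counts))
        s = _background_spectrum(n_peaks, config, rng, identifier=sid)
        spectra.append(s)
        truth_rows.append({"spectrum_id": sid, "label": "background", "variant": ""})
    truth = pd.DataFrame(truth_rows, columns=["spectrum_id", "label", "variant"])
    return spectra, truth
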