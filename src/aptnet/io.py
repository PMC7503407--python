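"""File I/O and run configuration.

MGF is the canonical interchange format (simple, textual); mzXML reading
is supported as well since converted vendor data commonly arrive that way.
Both go through pyteomics. Configuration is a single YAML document that
can override the building-block library, the position constraints, the
networking parameters and the simulation settings; omitted keys fall back
to the package defaults.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml
from pyteomics import mgf as _mgf
from pyteomics import mzxml as _mzxml

from .annotation import DEFAULT_TOL_PPM, Spectrum
from .networking import NetworkParams
from .scaffold import ResidueBlock, default_block_library
from .simulate import SimulationConfig
from .chem import parse_formula
from .variants import STUDY_CONSTRAINTS

__all__ = [
    "RunConfig",
    "read_spectra",
    "write_mgf",
    "load_config",
    "load_block_library",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything an end-to-end run needs."""

    input_spectra: Optional[Path] = None
    output_dir: Path = Path("aptnet_out")
    network: NetworkParams = field(default_factory=NetworkParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    constraints: Dict[str, List[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in STUDY_CONSTRAINTS.items()}
    )
    blocks: Dict[str, ResidueBlock] = field(default_factory=default_block_library)
    annotation_tol_ppm: float = DEFAULT_TOL_PPM
    merge_xle: bool = True


def _spectrum_from_entry(entry: dict, index: int, source: str) -> Optional[Spectrum]:
    params = entry.get("params", entry)
    if "pepmass" in params:
        pepmass = params["pepmass"]
        precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
    elif "precursorMz" in entry:  # mzXML
        precursor = float(entry["precursorMz"][0]["precursorMz"])
    else:
        return None
    charge = 1
    raw_charge = params.get("charge")
    if raw_charge:
        try:
            charge = abs(int(raw_charge[0]))
        except (TypeError, ValueError, IndexError):
            charge = 1
    identifier = str(
        params.get("title") or entry.get("id") or entry.get("num") or f"{source}#{index}"
    )
    mz = np.asarray(entry["m/z array"], dtype=float)
    intensity = np.asarray(entry["intensity array"], dtype=float)
    return Spectrum.from_arrays(identifier, precursor, mz, intensity, charge)


def read_spectra(path, fmt: Optional[str] = None) -> List[Spectrum]:
    """Read MS/MS spectra from an MGF or mzXML file.

    ``fmt`` is inferred from the extension when omitted. MS1 scans and
    entries without a precursor are skipped; the skipped count is logged.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {"mgf": "mgf", ".mgf": "mgf", ".mzxml": "mzxml"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer spectrum format from {path.name!r}")
    fmt = fmt.lower()
    spectra: List[Spectrum] = []
    skipped = 0
    if fmt == "mgf":
        with _mgf.MGF(str(path)) as reader:
            for i, entry in enumerate(reader):
                s = _spectrum_from_entry(entry, i, path.name)
                if s is None:
                    skipped += 1
                else:
                    spectra.append(s)
    elif fmt == "mzxml":
        with _mzxml.MzXML(str(path)) as reader:
            for i, entry in enumerate(reader):
                if int(entry.get("msLevel", 1)) < 2 or "precursorMz" not in entry:
                    skipped += 1
                    continue
                s = _spectrum_from_entry(entry, i, path.name)
                if s is None:
                    skipped += 1
                else:
                    spectra.append(s)
    else:
        raise ValueError(f"unsupported spectrum format: {fmt!r}")
    if skipped:
        logger.warning("%s: skipped %d entries without MS2 precursor", path.name, skipped)
    if not spectra:
        logger.warning("%s: no MS/MS spectra parsed", path.name)
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra to an MGF file (title, pepmass, charge, peak list)."""
    entries = [
        {
            "m/z array": s.mz_array,
            "intensity array": s.intensity_array,
            "params": {
                "title": s.identifier,
                "pepmass": s.precursor_mz,
                "charge": f"{s.precursor_charge}+",
            },
        }
        for s in spectra
    ]
    _mgf.write(entries, str(path), file_mode="w")


def load_block_library(spec: Dict[str, dict]) -> Dict[str, ResidueBlock]:
    """Build a block library from a config mapping:
    ``{name: {formula, positions, immonium: {label: formula}}}``."""
    library: Dict[str, ResidueBlock] = {}
    for name, entry in spec.items():
        immonium = tuple(
            (label, parse_formula(f)) for label, f in (entry.get("immonium") or {}).items()
        )
        library[name] = ResidueBlock(
            name=name,
            formula=parse_formula(entry["formula"]),
            allowed_positions=frozenset(entry["positions"]),
            immonium=immonium,
        )
    return library


def _dataclass_from_mapping(cls, mapping: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; missing sections use defaults."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    if "input_spectra" in raw and raw["input_spectra"]:
        cfg.input_spectra = Path(raw["input_spectra"])
    if "output_dir" in raw and raw["output_dir"]:
        cfg.output_dir = Path(raw["output_dir"])
    if "network" in raw:
        cfg.network = _dataclass_from_mapping(NetworkParams, raw["network"] or {})
    if "simulation" in raw:
        sim = dict(raw["simulation"] or {})
        if "noise_mz_range" in sim:
            sim["noise_mz_range"] = tuple(sim["noise_mz_range"])
        cfg.simulation = _dataclass_from_mapping(SimulationConfig, sim)
    if "blocks" in raw and raw["blocks"]:
        cfg.blocks = load_block_library(raw["blocks"])
    if "constraints" in raw and raw["constraints"]:
        cfg.constraints = {k: list(v) for k, v in raw["constraints"].items()}
    if "annotation_tol_ppm" in raw:
        cfg.annotation_tol_ppm = float(raw["annotation_tol_ppm"])
    if "merge_xle" in raw:
        cfg.merge_xle = bool(raw["merge_xle"])
    logger.info("loaded configuration from %s", path)
    return cfg
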