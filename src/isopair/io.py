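"""Readers and writers: spectra (two-column text, mzML), residue tables,
peptide definitions and provenance-stamped CSV output."""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import yaml

from .chem import ElementalComposition, PeptideSpecies, RESIDUE_FORMULAS, parse_formula
from .simulate import Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_residue_table",
    "load_peptides",
    "config_hash",
    "write_table",
    "SpectrumFormatError",
]

logger = logging.getLogger("isopair")


class SpectrumFormatError(ValueError):
    """A spectrum file could not be parsed."""


def _read_text_spectrum(path: Path) -> Spectrum:
    mz: List[float] = []
    intensity: List[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: expected two columns (m/z intensity), got {raw!r}"
                )
            try:
                mz.append(float(parts[0]))
                intensity.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumFormatError(f"{path}:{lineno}: {exc}") from exc
    return _as_spectrum(np.array(mz), np.array(intensity), {"source": str(path)})


# mzML binaryDataArray cvParam accessions
_MZML_ACCESSIONS = {
    "MS:1000514": ("kind", "mz"),
    "MS:1000515": ("kind", "intensity"),
    "MS:1000523": ("dtype", "<f8"),
    "MS:1000521": ("dtype", "<f4"),
    "MS:1000574": ("compression", "zlib"),
    "MS:1000576": ("compression", "none"),
}


def _decode_binary_array(elem) -> tuple[Optional[str], np.ndarray]:
    """Decode one <binaryDataArray>: returns (kind, values)."""
    import base64
    import zlib

    props = {"dtype": "<f8", "compression": "none", "kind": None}
    binary_text = ""
    for child in elem.iter():
        tag = child.tag.rsplit("}", 1)[-1]
        if tag == "cvParam":
            hit = _MZML_ACCESSIONS.get(child.get("accession"))
            if hit:
                props[hit[0]] = hit[1]
        elif tag == "binary" and child.text:
            binary_text = child.text.strip()
    raw = base64.b64decode(binary_text) if binary_text else b""
    if props["compression"] == "zlib":
        raw = zlib.decompress(raw)
    return props["kind"], np.frombuffer(raw, dtype=props["dtype"]).astype(float)


def _read_mzml_spectrum(path: Path, index: int = 0) -> Spectrum:
    """Minimal mzML reader: m/z and intensity arrays of one spectrum.

    Handles 32/64-bit little-endian floats with zlib or no compression —
    the encodings written by the common converters.
    """
    from lxml import etree

    i = -1
    for _, elem in etree.iterparse(str(path), events=("end",)):
        if elem.tag.rsplit("}", 1)[-1] != "spectrum":
            continue
        i += 1
        if i < index:
            elem.clear()
            continue
        arrays: Dict[str, np.ndarray] = {}
        for sub in elem.iter():
            if sub.tag.rsplit("}", 1)[-1] == "binaryDataArray":
                kind, values = _decode_binary_array(sub)
                if kind:
                    arrays[kind] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise SpectrumFormatError(
                f"{path}: spectrum {index} lacks m/z or intensity arrays"
            )
        return _as_spectrum(arrays["mz"], arrays["intensity"],
                            {"source": str(path), "mzml_index": index})
    raise SpectrumFormatError(f"{path}: no spectrum at index {index}")


def _as_spectrum(mz: np.ndarray, intensity: np.ndarray, metadata: dict) -> Spectrum:
    if mz.size and not np.all(np.diff(mz) > 0):
        logger.warning("m/z values not strictly increasing; sorting and merging duplicates")
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        uniq, inverse = np.unique(mz, return_inverse=True)
        if uniq.size != mz.size:
            intensity = np.bincount(inverse, weights=intensity)
            mz = uniq
        metadata = {**metadata, "sorted": True}
    return Spectrum(mz, intensity, metadata)


def read_spectrum(path: str | Path, format: Optional[str] = None, index: int = 0) -> Spectrum:
    """Read a spectrum from two-column text or mzML.

    ``format`` is inferred from the extension when omitted.  Text files may
    be whitespace- or comma-delimited with ``#`` comments.  Out-of-order
    m/z rows are sorted and duplicate m/z merged by intensity sum, with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mzml" if path.suffix.lower() == ".mzml" else "text"
    if format == "mzml":
        return _read_mzml_spectrum(path, index)
    if format == "text":
        return _read_text_spectrum(path)
    raise ValueError(f"unknown spectrum format {format!r}; expected 'text' or 'mzml'")


def write_spectrum(s: Spectrum, path: str | Path, header: Mapping[str, object] | None = None) -> None:
    """Write a spectrum as two-column text with a ``#`` provenance header."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}: {value}\n")
        for m, i in zip(s.mz, s.intensity):
            fh.write(f"{m:.6f} {i:.8g}\n")


def read_residue_table(path: str | Path) -> Dict[str, ElementalComposition]:
    """Read a residue-formula CSV with columns ``code,formula`` (Hill notation).

    The returned table extends the built-in canonical-residue table; user
    entries override built-ins of the same code.
    """
    table = dict(RESIDUE_FORMULAS)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"code", "formula"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: residue table needs 'code' and 'formula' columns")
        for row in reader:
            table[row["code"].strip()] = parse_formula(row["formula"].strip())
    return table


def load_peptides(
    path: str | Path,
    residue_formulas: Mapping[str, ElementalComposition] | None = None,
) -> Dict[str, PeptideSpecies]:
    """Load peptide definitions from a YAML/JSON config.

    Each entry: ``{name, sequence, n_terminus, c_terminus}``; terminal
    fields default to acetyl_light / amide, the tagged-shuttle design.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    entries = data.get("peptides", data) if isinstance(data, dict) else data
    table = dict(residue_formulas) if residue_formulas else RESIDUE_FORMULAS
    peptides: Dict[str, PeptideSpecies] = {}
    for entry in entries:
        name = entry.get("name", entry["sequence"])
        peptides[name] = PeptideSpecies(
            sequence=entry["sequence"],
            n_terminus=entry.get("n_terminus", "acetyl_light"),
            c_terminus=entry.get("c_terminus", "amide"),
            residue_formulas=table,
            name=name,
        )
    return peptides


def config_hash(obj: object) -> str:
    """Short deterministic hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(rows: List[dict], path: str | Path, provenance: Mapping[str, object]) -> None:
    """Write a tidy CSV preceded by ``#``-prefixed provenance lines."""
    path = Path(path)
    fieldnames = list(rows[0].keys()) if rows else []
    with open(path, "w", newline="") as fh:
        for key, value in provenance.items():
            fh.write(f"# {key}: {value}\n")
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)


def read_table(path: str | Path) -> List[dict]:
    """Read a CSV written by :func:`write_table`, skipping ``#`` lines."""
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.DictReader(lines)
    return list(reader)
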