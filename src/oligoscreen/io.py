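"""Readers, writers and workflow configuration.

Spectra come in either as centroided mzML (read through pyteomics; profile
data is rejected, centroiding is an upstream conversion step) or as plain
CSV peak lists.  Results leave as CSV/JSON bundles whose headers record the
package version, a hash of the configuration, and the seed, so a run can be
reproduced from its outputs alone.

The mzML writer emits a minimal centroid-mode document (64-bit float
arrays, no compression) sufficient for round-tripping simulated spectra
through standard mzML readers.  The reader is a small namespace-agnostic
parser for centroided mzML covering the encodings such files use in
practice (64/32-bit float binary arrays, zlib or no compression).

CSV dialect throughout: comma separated, UTF-8, "." decimal; m/z columns
are positive-ion observed values (electron-mass corrected).
"""

from __future__ import annotations

import base64
import hashlib
import json
import struct
import warnings
import zlib
import xml.etree.ElementTree as ET
from dataclasses import asdict, dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .di import CentroidSpectrum

__all__ = [
    "WorkflowConfig",
    "config_hash",
    "read_peaklist_csv",
    "write_peaklist_csv",
    "write_mzml",
    "read_mzml_centroids",
    "write_report",
    "read_report_csv",
]


@dataclass(frozen=True)
class WorkflowConfig:
    """Top-level workflow parameters, serialisable to YAML."""

    di_tol_da: float = 0.001
    lc_tol_ppm: float = 5.0
    min_intensity: float = 1e4
    adducts: tuple[str, ...] = ("[M+NH4]+", "[M+H]+", "[M+Na]+", "[M+2NH4]2+")
    charges: tuple[int, ...] = (1, 2)
    min_sequence_length: int = 2
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self):
        if self.di_tol_da <= 0 or self.lc_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")
        if self.min_intensity < 0:
            raise ValueError("intensity threshold must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "WorkflowConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["adducts"] = tuple(raw.get("adducts", cls.adducts))
        raw["charges"] = tuple(raw.get("charges", cls.charges))
        return cls(**raw)


def config_hash(config: WorkflowConfig) -> str:
    """Stable short hash of the canonical config serialisation."""
    canonical = json.dumps(asdict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


# -- CSV peak lists -------------------------------------------------------

def read_peaklist_csv(path) -> CentroidSpectrum:
    """Read a two-column (mz, intensity) peak list.

    Rejects rather than coerces: missing columns and non-numeric rows raise
    with the offending row number.  Output is sorted with duplicates within
    1e-6 Da merged (intensities summed).
    """
    table = pd.read_csv(path)
    missing = {"mz", "intensity"} - set(table.columns)
    if missing:
        raise ValueError(f"peak list {path} missing columns: {sorted(missing)}")
    for col in ("mz", "intensity"):
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = numeric.isna() & table[col].notna() | table[col].isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based plus header line
            raise ValueError(f"non-numeric {col} value at line {row} of {path}")
        table[col] = numeric
    return CentroidSpectrum(table["mz"].to_numpy(), table["intensity"].to_numpy())


def write_peaklist_csv(spectrum: CentroidSpectrum, path) -> None:
    spectrum.to_frame().to_csv(path, index=False)


# -- mzML -----------------------------------------------------------------

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="oligoscreen" version="{version}"/>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="oligoscreen"/>
    </dataProcessing>
  </dataProcessingList>
  <run id="{run_id}" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{count}" defaultDataProcessingRef="DP1">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _encode_array(values: np.ndarray) -> str:
    packed = struct.pack(f"<{len(values)}d", *values.astype(float))
    return base64.b64encode(packed).decode()


def write_mzml(spectra: list[CentroidSpectrum] | CentroidSpectrum, path, run_id="run1") -> None:
    """Write centroid spectra as minimal mzML."""
    if isinstance(spectra, CentroidSpectrum):
        spectra = [spectra]
    parts = [_MZML_HEADER.format(version=__version__, run_id=escape(str(run_id)), count=len(spectra))]
    for index, spectrum in enumerate(spectra):
        mz_b64 = _encode_array(spectrum.mz)
        int_b64 = _encode_array(spectrum.intensity)
        parts.append(
            f"""      <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{len(spectrum)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(int_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""
        )
    parts.append(_MZML_FOOTER)
    Path(path).write_text("".join(parts), encoding="utf-8")


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(element, path) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind, values)."""
    names = set()
    text = ""
    for child in element.iter():
        local = _localname(child.tag)
        if local == "cvParam":
            names.add(child.get("name", ""))
        elif local == "binary":
            text = child.text or ""
    raw = base64.b64decode(text) if text else b""
    if "zlib compression" in names:
        raw = zlib.decompress(raw)
    elif "no compression" not in names and raw:
        raise ValueError(f"{path}: unsupported binary compression ({sorted(names)})")
    if "64-bit float" in names or not names & {"32-bit float"}:
        values = np.frombuffer(raw, dtype="<f8")
    else:
        values = np.frombuffer(raw, dtype="<f4").astype(float)
    kind = None
    if "m/z array" in names:
        kind = "mz"
    elif "intensity array" in names:
        kind = "intensity"
    return kind, values


def read_mzml_centroids(path) -> list[CentroidSpectrum]:
    """Read centroided spectra from an mzML file.

    Profile-mode spectra are rejected with an explicit error: centroiding
    is an upstream conversion step, not something this package attempts.
    Malformed XML raises a parse error carrying the file position.
    """
    spectra = []
    try:
        context = ET.iterparse(str(path), events=("end",))
        for _, element in context:
            if _localname(element.tag) != "spectrum":
                continue
            params = {
                child.get("name", "")
                for child in element.iter()
                if _localname(child.tag) == "cvParam"
            }
            if "profile spectrum" in params:
                raise ValueError(
                    f"{path}: spectrum {element.get('id')!r} is profile mode; "
                    "centroided input is required (convert upstream)"
                )
            arrays: dict[str, np.ndarray] = {}
            for sub in element.iter():
                if _localname(sub.tag) == "binaryDataArray":
                    kind, values = _decode_binary_array(sub, path)
                    if kind:
                        arrays[kind] = values
            if "mz" not in arrays or "intensity" not in arrays:
                raise ValueError(
                    f"{path}: spectrum {element.get('id')!r} lacks m/z or "
                    "intensity arrays"
                )
            spectra.append(
                CentroidSpectrum(
                    arrays["mz"],
                    arrays["intensity"],
                    {"id": element.get("id"), "polarity": "positive"},
                )
            )
            element.clear()
    except ET.ParseError as exc:
        raise ValueError(f"{path}: malformed mzML ({exc})") from exc
    if not spectra:
        warnings.warn(f"{path}: no spectra found", stacklevel=2)
    return spectra


# -- reports --------------------------------------------------------------

_FLOAT_FORMATS = {"mz": "%.5f", "error_ppm": "%.2f"}


def _header_lines(config: WorkflowConfig | None, seed: int | None) -> str:
    lines = [f"# oligoscreen v{__version__}"]
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    lines.append("# m/z values are positive-ion observed values (electron-mass corrected)")
    return "\n".join(lines) + "\n"


def write_report(
    out_dir,
    components: pd.DataFrame | None = None,
    annotations: pd.DataFrame | None = None,
    quant: pd.DataFrame | None = None,
    composition: pd.DataFrame | None = None,
    config: WorkflowConfig | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write the result bundle; returns the paths written.

    Every CSV starts with commented metadata lines (version, config hash,
    seed); an empty table still produces a headers-only file.
    """
    tables = {
        "components": components,
        "annotations": annotations,
        "quantification": quant,
        "composition": composition,
    }
    if all(v is None for v in tables.values()):
        raise ValueError("write_report needs at least one table")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    header = _header_lines(config, seed)
    for name, table in tables.items():
        if table is None:
            continue
        path = out_dir / f"{name}.csv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            table.to_csv(fh, index=isinstance(table.index, pd.MultiIndex) or table.index.name is not None)
        written[name] = path
    meta = {
        "version": __version__,
        "config_hash": config_hash(config) if config else None,
        "seed": seed,
        "tables": sorted(written),
    }
    meta_path = out_dir / "metadata.json"
    meta_path.write_text(json.dumps(meta, indent=1))
    written["metadata"] = meta_path
    return written


def read_report_csv(path) -> pd.DataFrame:
    """Read back a report CSV, skipping the commented metadata header."""
    return pd.read_csv(path, comment="#")
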