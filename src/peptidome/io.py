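"""Spectrum and tabular I/O.

Spectra are exchanged as mzML (read via pyteomics, written by a minimal
built-in writer) or as two-column (m/z, intensity) text, optionally
gzip-compressed.  Feature matrices, cohort metadata and reports travel as
TSV so that every artifact of a run is a plain-text file.
"""

from __future__ import annotations

import base64
import gzip
import struct
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from xml.sax.saxutils import escape, quoteattr

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumFormatError",
    "NullSpectrumError",
    "FeatureMatrix",
    "read_spectrum",
    "write_spectrum",
    "read_spectra_mzml",
    "write_spectra_mzml",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_metadata",
    "write_metadata",
]

VALID_GROUPS = ("control", "benign", "ccRCC", "non-ccRCC-malignant")


class SpectrumFormatError(ValueError):
    """A spectrum file or record could not be parsed."""


class NullSpectrumError(ValueError):
    """Spectrum carries no usable signal (empty or all-zero intensities)."""


@dataclass
class Spectrum:
    """One acquisition: m/z and intensity arrays plus acquisition metadata.

    ``mode`` is ``"linear"`` (broad, isotopically unresolved profiles,
    average-mass regime) or ``"reflector"`` (isotopically resolved,
    monoisotopic regime).
    """

    mz: np.ndarray
    intensity: np.ndarray
    mode: str = "linear"
    subject_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size == 0 or self.intensity.size == 0:
            raise NullSpectrumError(
                f"null spectrum (subject={self.subject_id!r}, "
                f"replicate={self.replicate_id!r}): empty arrays"
            )
        if self.mz.shape != self.intensity.shape:
            raise SpectrumFormatError(
                f"m/z and intensity lengths differ: {self.mz.size} vs {self.intensity.size}"
            )
        if not (np.isfinite(self.mz).all() and np.isfinite(self.intensity).all()):
            raise SpectrumFormatError("non-finite values in spectrum arrays")
        if self.mode not in ("linear", "reflector"):
            raise ValueError(f"unknown mode {self.mode!r}")
        d = np.diff(self.mz)
        if np.any(d <= 0):
            # repair: sort and drop duplicate m/z values, keeping the first
            warnings.warn(
                f"non-monotone m/z axis repaired (subject={self.subject_id!r})",
                stacklevel=2,
            )
            order = np.argsort(self.mz, kind="stable")
            mz, idx = np.unique(self.mz[order], return_index=True)
            self.mz = mz
            self.intensity = self.intensity[order][idx]

    def __len__(self) -> int:
        return int(self.mz.size)

    def with_intensity(self, intensity: np.ndarray) -> "Spectrum":
        return replace(self, intensity=np.asarray(intensity, dtype=float))

    def total_intensity(self) -> float:
        return float(self.intensity.sum())


# ---------------------------------------------------------------------------
# xy-text  (whitespace/tab separated, '#' comments, optional header line)

def _read_spectrum_xy(path: Path, **meta) -> Spectrum:
    opener = gzip.open if path.suffix == ".gz" else open
    mz, inten = [], []
    with opener(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise SpectrumFormatError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                mz.append(float(parts[0]))
                inten.append(float(parts[1]))
            except ValueError:
                if not mz:  # tolerated single header line
                    continue
                raise SpectrumFormatError(
                    f"{path}:{lineno}: non-numeric record {line!r}"
                ) from None
    if not mz:
        raise NullSpectrumError(f"{path}: null spectrum (no data rows)")
    return Spectrum(np.asarray(mz), np.asarray(inten), **meta)


def _write_spectrum_xy(s: Spectrum, path: Path) -> None:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write(f"# subject={s.subject_id} replicate={s.replicate_id} mode={s.mode}\n")
        for m, i in zip(s.mz, s.intensity):
            fh.write(f"{float(m)!r}\t{float(i)!r}\n")


# ---------------------------------------------------------------------------
# mzML.  A self-contained reader/writer pair: binary data arrays are
# little-endian 32/64-bit floats, base64-encoded, zlib or uncompressed,
# tagged with the standard PSI-MS CV accessions.  The reader is namespace-
# agnostic and ignores everything it does not need.


def _decode_meta(spectrum_id: str) -> dict:
    meta = {}
    for tok in spectrum_id.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            if k in ("subject", "replicate", "mode"):
                meta[{"subject": "subject_id", "replicate": "replicate_id", "mode": "mode"}[k]] = v
    return meta


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(elem, context: str) -> tuple[str | None, np.ndarray]:
    """One <binaryDataArray>: (array kind, decoded values)."""
    import zlib

    dtype, compressed, kind, payload = "d", False, None, None
    for child in elem.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":
                dtype = "f"  # 32-bit float
            elif acc == "MS:1000523":
                dtype = "d"
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif name == "binary":
            payload = child.text or ""
    if payload is None:
        raise SpectrumFormatError(f"{context}: binaryDataArray without <binary>")
    try:
        raw = base64.b64decode(payload)
        if compressed:
            raw = zlib.decompress(raw)
        values = np.frombuffer(raw, dtype=np.dtype("<" + dtype)).astype(float)
    except Exception as exc:
        raise SpectrumFormatError(f"{context}: undecodable binary data ({exc})") from exc
    return kind, values


def read_spectra_mzml(path) -> list[Spectrum]:
    from xml.etree import ElementTree

    out = []
    try:
        root = ElementTree.parse(str(path)).getroot()
    except ElementTree.ParseError as exc:
        raise SpectrumFormatError(f"{path}: not well-formed mzML ({exc})") from exc
    for elem in root.iter():
        if _local(elem.tag) != "spectrum":
            continue
        sid = elem.get("id", "")
        arrays: dict[str, np.ndarray] = {}
        for sub in elem.iter():
            if _local(sub.tag) == "binaryDataArray":
                kind, values = _decode_binary_array(sub, f"{path} spectrum {sid!r}")
                if kind:
                    arrays[kind] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise SpectrumFormatError(
                f"{path}: spectrum {sid!r} lacks m/z or intensity array"
            )
        out.append(Spectrum(arrays["mz"], arrays["intensity"], **_decode_meta(sid)))
    if not out:
        raise SpectrumFormatError(f"{path}: no spectra found")
    return out


def _b64(arr: np.ndarray) -> str:
    raw = struct.pack(f"<{arr.size}d", *map(float, arr))
    return base64.b64encode(raw).decode("ascii")


def write_spectra_mzml(spectra: list[Spectrum], path) -> None:
    chunks = [
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        '  <cvList count="1">\n'
        '    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/'
        'HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>\n'
        "  </cvList>\n"
        '  <run id="run1">\n'
        f'    <spectrumList count="{len(spectra)}">\n'
    ]
    for i, s in enumerate(spectra):
        sid = quoteattr(f"subject={s.subject_id} replicate={s.replicate_id} mode={s.mode} scan={i}")
        chunks.append(
            f'      <spectrum index="{i}" id={sid} defaultArrayLength="{len(s)}">\n'
            '        <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>\n'
            '        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>\n'
            '        <binaryDataArrayList count="2">\n'
        )
        for accession, name, arr in (
            ("MS:1000514", "m/z array", s.mz),
            ("MS:1000515", "intensity array", s.intensity),
        ):
            b = _b64(arr)
            chunks.append(
                f'          <binaryDataArray encodedLength="{len(b)}">\n'
                '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
                '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
                f'            <cvParam cvRef="MS" accession="{accession}" name="{escape(name)}" value=""/>\n'
                f"            <binary>{b}</binary>\n"
                "          </binaryDataArray>\n"
            )
        chunks.append("        </binaryDataArrayList>\n      </spectrum>\n")
    chunks.append("    </spectrumList>\n  </run>\n</mzML>\n")
    Path(path).write_text("".join(chunks))


def read_spectrum(path, format: str | None = None, **meta) -> Spectrum:
    """Read a single spectrum; format inferred from the extension if not given.

    mzML files holding several spectra yield the first one (use
    :func:`read_spectra_mzml` for the full list).
    """
    path = Path(path)
    if format is None:
        format = "mzML" if path.suffix.lower() == ".mzml" else "xy-text"
    if format == "mzML":
        return read_spectra_mzml(path)[0]
    if format == "xy-text":
        return _read_spectrum_xy(path, **meta)
    raise ValueError(f"unknown spectrum format {format!r}")


def write_spectrum(s: Spectrum, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "mzML" if path.suffix.lower() == ".mzml" else "xy-text"
    if format == "mzML":
        write_spectra_mzml([s], path)
    elif format == "xy-text":
        _write_spectrum_xy(s, path)
    else:
        raise ValueError(f"unknown spectrum format {format!r}")


# ---------------------------------------------------------------------------
# Feature matrix: subjects x consensus-peak areas, with joined covariates.

@dataclass
class FeatureMatrix:
    """Subjects × consensus-peak areas plus group/age/sex covariates.

    ``areas`` is indexed by subject id with one column per consensus-peak
    label (nominal-mass strings such as ``"1670"``); ``metadata`` is indexed
    identically with columns ``group``, ``age``, ``sex``.  Absent peaks are
    stored as area 0, never as missing cells.
    """

    areas: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.areas.index.has_duplicates:
            dups = self.areas.index[self.areas.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate subject rows: {dups}")
        if self.areas.columns.has_duplicates:
            raise ValueError("duplicate feature labels")
        if self.areas.isna().any().any():
            raise ValueError("missing cells in feature matrix")
        if not self.metadata.empty:
            missing = self.areas.index.difference(self.metadata.index)
            if len(missing):
                raise ValueError(f"subjects without metadata: {missing.tolist()}")
            self.metadata = self.metadata.loc[self.areas.index]

    @property
    def subjects(self) -> list[str]:
        return list(self.areas.index)

    @property
    def features(self) -> list[str]:
        return list(self.areas.columns)

    def select_features(self, labels) -> "FeatureMatrix":
        return FeatureMatrix(self.areas[list(labels)].copy(), self.metadata.copy())

    def select_subjects(self, ids) -> "FeatureMatrix":
        ids = list(ids)
        return FeatureMatrix(
            self.areas.loc[ids].copy(),
            self.metadata.loc[ids].copy() if not self.metadata.empty else pd.DataFrame(),
        )


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    df = matrix.areas.copy()
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_feature_matrix(path, metadata: pd.DataFrame | None = None) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col="subject_id", dtype={"subject_id": str})
    df.columns = [str(c) for c in df.columns]
    bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
    for col in bad:
        rows = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
        raise SpectrumFormatError(f"{path}: non-numeric cell(s) in column {col!r}, row(s) {rows}")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate subject rows")
    return FeatureMatrix(df, metadata if metadata is not None else pd.DataFrame())


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", index_col="subject_id", dtype={"subject_id": str})
    md.index = md.index.astype(str)
    if md.index.has_duplicates:
        raise ValueError(f"{path}: duplicate subject ids")
    if "age" in md.columns and (md["age"] <= 0).any():
        raise ValueError(f"{path}: non-positive ages")
    if "group" in md.columns:
        unknown = set(md["group"]) - set(VALID_GROUPS)
        if unknown:
            raise ValueError(f"{path}: unknown group labels {sorted(unknown)}")
    return md
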