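"""Readers and writers for the pipeline's file formats.

Spectra: mzML (read, minimal stdlib parser) or a plain two-column text dialect
(read/write). Peak tables, aligned matrices and compound databases travel as
CSV. All CSV/JSON writers are deterministic, so a write -> read -> write
round trip is byte-identical.

Two-column text dialect
-----------------------
One file per injection::

    # sample=A01 replicate=r1
    # scan=0
    100.00 1234.5
    100.01 1250.1
    # scan=1
    ...

``# scan=K`` lines open each scan block; every scan must repeat the same
m/z grid. The optional first header line carries sample/replicate ids.
"""

from __future__ import annotations

import base64
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import AlignedMatrix
from .annotation import Annotation, CompoundDB
from .preprocessing import PeakTable, RawSpectrum

__all__ = [
    "read_spectrum_text",
    "write_spectrum_text",
    "read_spectrum_mzml",
    "read_spectrum",
    "write_peak_table",
    "read_peak_tables",
    "write_aligned_matrix",
    "read_aligned_matrix",
    "write_features_sidecar",
    "read_compound_db",
    "write_compound_db",
    "write_annotations",
]

_FLOAT_FMT = "%.6g"


def write_spectrum_text(spec: RawSpectrum, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sample={spec.sample_id} replicate={spec.replicate_id}\n")
        for k in range(spec.n_scans):
            fh.write(f"# scan={k}\n")
            for m, v in zip(spec.mz, spec.intensities[k]):
                fh.write(f"{float(m)!r} {float(v)!r}\n")


def read_spectrum_text(path) -> RawSpectrum:
    path = Path(path)
    sample_id, replicate_id = path.stem, ""
    scans: list[list[tuple[float, float]]] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("scan="):
                    scans.append([])
                else:
                    for tok in body.split():
                        if tok.startswith("sample="):
                            sample_id = tok.split("=", 1)[1]
                        elif tok.startswith("replicate="):
                            replicate_id = tok.split("=", 1)[1]
                continue
            if not scans:
                scans.append([])
            a, b = line.split()
            scans[-1].append((float(a), float(b)))
    if not scans or not scans[0]:
        raise ValueError(f"{path}: no scan data")
    mz = np.asarray([p[0] for p in scans[0]])
    inten = np.asarray([[p[1] for p in scan] for scan in scans])
    for scan in scans[1:]:
        if len(scan) != mz.size or not np.allclose([p[0] for p in scan], mz):
            raise ValueError(f"{path}: scans do not share one m/z grid")
    return RawSpectrum(sample_id, replicate_id, mz, inten)


def _decode_binary_array(bda_elem) -> tuple[str | None, np.ndarray]:
    """Decode one mzML <binaryDataArray>: returns (array kind, values).

    Supports 32/64-bit floats, zlib or no compression; kind is "mz",
    "intensity", or None for other array types.
    """
    import zlib

    dtype = "<f8"
    compressed = False
    kind = None
    binary_text = ""
    for child in bda_elem.iter():
        tag = child.tag.rsplit("}", 1)[-1]
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":
                dtype = "<f4"
            elif acc == "MS:1000523":
                dtype = "<f8"
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif tag == "binary":
            binary_text = child.text or ""
    raw = base64.b64decode(binary_text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_spectrum_mzml(path, sample_id: str | None = None, replicate_id: str = "") -> RawSpectrum:
    """Read an mzML file whose scans share one m/z grid.

    Minimal namespace-agnostic stdlib parser: walks <spectrum> elements and
    decodes their m/z and intensity binary arrays (32/64-bit floats, zlib or
    no compression). Avoids optional parser dependencies so mzML input works
    in offline environments.
    """
    import xml.etree.ElementTree as ET

    path = Path(path)
    scans = []
    mz = None
    root = ET.parse(str(path)).getroot()
    for spectrum in root.iter():
        if spectrum.tag.rsplit("}", 1)[-1] != "spectrum":
            continue
        arrays: dict[str, np.ndarray] = {}
        for bda in spectrum.iter():
            if bda.tag.rsplit("}", 1)[-1] == "binaryDataArray":
                kind, vals = _decode_binary_array(bda)
                if kind is not None:
                    arrays[kind] = vals
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(f"{path}: spectrum without m/z or intensity array")
        m, i = arrays["mz"], arrays["intensity"]
        if mz is None:
            mz = m
        elif m.size != mz.size or not np.allclose(m, mz):
            raise ValueError(f"{path}: scans do not share one m/z grid")
        scans.append(i)
    if mz is None:
        raise ValueError(f"{path}: no spectra found")
    return RawSpectrum(sample_id or path.stem, replicate_id, mz, np.vstack(scans))


def read_spectrum(path) -> RawSpectrum:
    """Dispatch on extension: .mzml -> mzML reader, otherwise text dialect."""
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        return read_spectrum_mzml(path)
    return read_spectrum_text(path)


def spectra_to_mzml_xml(spectra_scans: list[tuple[np.ndarray, np.ndarray]]) -> str:
    """Serialize scans as a minimal mzML document (64-bit, base64, no zlib).

    Deliberately small: enough structure for standard readers to recover the
    m/z and intensity arrays; used to build test inputs programmatically.
    """

    def b64(arr: np.ndarray) -> str:
        raw = struct.pack(f"<{arr.size}d", *map(float, arr))
        return base64.b64encode(raw).decode()

    parts = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<run id="run1">',
        f'<spectrumList count="{len(spectra_scans)}">',
    ]
    for k, (mz, inten) in enumerate(spectra_scans):
        parts.append(
            f'<spectrum index="{k}" id="scan={k}" defaultArrayLength="{mz.size}">'
        )
        parts.append('<cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum"/>')
        parts.append('<binaryDataArrayList count="2">')
        for arr, acc, name in (
            (mz, "MS:1000514", "m/z array"),
            (inten, "MS:1000515", "intensity array"),
        ):
            enc = b64(np.asarray(arr))
            parts.append(f'<binaryDataArray encodedLength="{len(enc)}">')
            parts.append('<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>')
            parts.append('<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>')
            parts.append(f'<cvParam cvRef="MS" accession="{acc}" name="{name}"/>')
            parts.append(f"<binary>{enc}</binary>")
            parts.append("</binaryDataArray>")
        parts.append("</binaryDataArrayList>")
        parts.append("</spectrum>")
    parts += ["</spectrumList>", "</run>", "</mzML>"]
    return "\n".join(parts)


def write_peak_table(table: PeakTable, path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": table.sample_id,
            "replicate_id": table.replicate_id,
            "mz": table.mz,
            "height": table.height,
        }
    )
    df.to_csv(path, index=False)


def read_peak_tables(paths) -> list[PeakTable]:
    """Read one or more PeakTable CSVs; files may hold several spectra."""
    tables = []
    for path in paths:
        df = pd.read_csv(
            path,
            dtype={"sample_id": str, "replicate_id": str},
            float_precision="round_trip",
        )
        df["replicate_id"] = df["replicate_id"].fillna("")
        for (sid, rid), grp in df.groupby(["sample_id", "replicate_id"], sort=False):
            grp = grp.sort_values("mz")
            tables.append(
                PeakTable(str(sid), str(rid), grp["mz"].to_numpy(), grp["height"].to_numpy())
            )
    return tables


def write_aligned_matrix(matrix: AlignedMatrix, path) -> None:
    """CSV: sample_id, class_label[, replicate_id], then one column per feature."""
    cols = {"sample_id": matrix.sample_ids, "class_label": matrix.class_labels}
    if matrix.replicate_ids is not None:
        cols["replicate_id"] = matrix.replicate_ids
    df = pd.DataFrame(cols)
    for j, fmz in enumerate(matrix.feature_mz):
        df[f"{fmz:.6f}"] = matrix.intensities[:, j]
    df.to_csv(path, index=False)


def read_aligned_matrix(path) -> AlignedMatrix:
    df = pd.read_csv(
        path,
        dtype={"sample_id": str, "class_label": str},
        float_precision="round_trip",
    )
    meta = ["sample_id", "class_label"]
    replicate_ids = None
    if "replicate_id" in df.columns:
        meta.append("replicate_id")
        replicate_ids = df["replicate_id"].fillna("").astype(str).tolist()
    feat_cols = [c for c in df.columns if c not in meta]
    return AlignedMatrix(
        sample_ids=df["sample_id"].tolist(),
        class_labels=df["class_label"].fillna("").tolist(),
        feature_mz=np.asarray([float(c) for c in feat_cols]),
        intensities=df[feat_cols].to_numpy(dtype=float),
        replicate_ids=replicate_ids,
    )


def write_features_sidecar(matrix: AlignedMatrix, n_members: np.ndarray | None, path) -> None:
    df = pd.DataFrame(
        {
            "feature_id": np.arange(matrix.n_features),
            "consensus_mz": [f"{v:.6f}" for v in matrix.feature_mz],
            "n_member_peaks": (
                n_members
                if n_members is not None
                else (matrix.intensities > 0).sum(axis=0)
            ),
        }
    )
    df.to_csv(path, index=False)


def read_compound_db(path) -> CompoundDB:
    df = pd.read_csv(path, float_precision="round_trip")
    name_col, mz_col = df.columns[0], df.columns[1]
    return CompoundDB(
        names=df[name_col].astype(str).tolist(),
        theoretical_mz=df[mz_col].to_numpy(dtype=float),
    )


def write_compound_db(db: CompoundDB, path) -> None:
    pd.DataFrame({"name": db.names, "theoretical_mz": db.theoretical_mz}).to_csv(
        path, index=False
    )


def write_annotations(annotations: list[Annotation], path) -> None:
    df = pd.DataFrame(
        [
            {
                "feature_id": a.feature_id,
                "feature_mz": f"{a.feature_mz:.6f}",
                "name": a.name,
                "ppm_error": f"{a.ppm:.3f}",
                "ambiguous": a.ambiguous,
            }
            for a in annotations
        ],
        columns=["feature_id", "feature_mz", "name", "ppm_error", "ambiguous"],
    )
    df.to_csv(path, index=False)
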