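"""Reading, writing and validation of centroided LC/MS acquisitions.

A run is an ordered list of scans; each scan holds parallel m/z and
intensity arrays at one retention time. Two on-disk representations are
supported: mzML (MS1 centroid spectra) and a plain TSV scan table with
columns ``scan_index, rt_min, mz, intensity``. Both round-trip exactly
(float64 values are serialized losslessly) and both feed the same
downstream fingerprint extraction.
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree


class MSFormatError(ValueError):
    """Raised when a file or in-memory run violates the acquisition model."""


@dataclass(frozen=True)
class Scan:
    """One centroided spectrum: retention time plus (m/z, intensity) pairs."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise MSFormatError(
                f"scan at rt={self.rt}: m/z and intensity arrays must be "
                f"1-D and equal length (got {mz.shape} vs {inten.shape})"
            )
        if self.rt < 0:
            raise MSFormatError(f"scan has negative retention time {self.rt}")
        if np.any(inten < 0):
            raise MSFormatError(
                f"scan at rt={self.rt} contains negative intensity"
            )
        if not (np.all(np.isfinite(mz)) and np.all(np.isfinite(inten))):
            raise MSFormatError(f"scan at rt={self.rt} contains non-finite values")


@dataclass
class MassSpecRun:
    """One individual's acquisition: scans strictly ordered by retention time."""

    individual_id: str
    scans: list[Scan] = field(default_factory=list)

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        for i in range(1, len(rts)):
            if rts[i] <= rts[i - 1]:
                raise MSFormatError(
                    f"run {self.individual_id!r}: scans not strictly ordered by "
                    f"rt at index {i} (rt {rts[i]} after {rts[i - 1]})"
                )

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    @property
    def acquisition_window(self) -> tuple[float, float]:
        if not self.scans:
            raise MSFormatError(f"run {self.individual_id!r} has no scans")
        return (self.scans[0].rt, self.scans[-1].rt)

    @property
    def mz_range(self) -> tuple[float, float]:
        lows = [s.mz.min() for s in self.scans if s.mz.size]
        highs = [s.mz.max() for s in self.scans if s.mz.size]
        if not lows:
            raise MSFormatError(f"run {self.individual_id!r} has no peaks")
        return (float(min(lows)), float(max(highs)))


# ---------------------------------------------------------------------------
# scan-table TSV
# ---------------------------------------------------------------------------

_SCAN_TABLE_COLS = ["scan_index", "rt_min", "mz", "intensity"]


def _read_scan_table(path: Path, individual_id: str) -> MassSpecRun:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _SCAN_TABLE_COLS if c not in df.columns]
    if missing:
        raise MSFormatError(f"{path}: scan table missing columns {missing}")
    scans = []
    for (idx, rt), grp in df.groupby(["scan_index", "rt_min"], sort=True):
        try:
            scans.append(Scan(rt=float(rt),
                              mz=grp["mz"].to_numpy(float),
                              intensity=grp["intensity"].to_numpy(float)))
        except MSFormatError as e:
            raise MSFormatError(f"{path}: scan {idx}: {e}") from e
    return MassSpecRun(individual_id=individual_id, scans=scans)


def _write_scan_table(run: MassSpecRun, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SCAN_TABLE_COLS) + "\n")
        for i, scan in enumerate(run.scans):
            for mz, inten in zip(scan.mz, scan.intensity):
                # %.17g round-trips float64 exactly
                fh.write(f"{i}\t{scan.rt:.17g}\t{mz:.17g}\t{inten:.17g}\n")


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _encode_array(values: np.ndarray) -> str:
    return base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode()


def _write_mzml(run: MassSpecRun, path: Path) -> None:
    root = etree.Element("mzML", nsmap={None: _MZML_NS}, version="1.1.0")
    etree.SubElement(root, "cvList", count="1")
    run_el = etree.SubElement(root, "run", id=run.individual_id)
    speclist = etree.SubElement(
        run_el, "spectrumList", count=str(run.n_scans)
    )
    for i, scan in enumerate(run.scans):
        spec = etree.SubElement(
            speclist, "spectrum", index=str(i),
            id=f"scan={i}", defaultArrayLength=str(scan.mz.size),
        )
        for acc, name in (("MS:1000511", "ms level"), ("MS:1000127", "centroid spectrum")):
            cv = etree.SubElement(spec, "cvParam", cvRef="MS", accession=acc, name=name)
            if acc == "MS:1000511":
                cv.set("value", "1")
            else:
                cv.set("value", "")
        scanlist = etree.SubElement(spec, "scanList", count="1")
        scan_el = etree.SubElement(scanlist, "scan")
        etree.SubElement(
            scan_el, "cvParam", cvRef="MS", accession="MS:1000016",
            name="scan start time", value=f"{scan.rt:.17g}",
            unitCvRef="UO", unitAccession="UO:0000031", unitName="minute",
        )
        badl = etree.SubElement(spec, "binaryDataArrayList", count="2")
        for arr, acc, name in (
            (scan.mz, "MS:1000514", "m/z array"),
            (scan.intensity, "MS:1000515", "intensity array"),
        ):
            encoded = _encode_array(arr)
            bda = etree.SubElement(
                badl, "binaryDataArray", encodedLength=str(len(encoded))
            )
            etree.SubElement(bda, "cvParam", cvRef="MS",
                             accession="MS:1000523", name="64-bit float", value="")
            etree.SubElement(bda, "cvParam", cvRef="MS",
                             accession="MS:1000576", name="no compression", value="")
            etree.SubElement(bda, "cvParam", cvRef="MS",
                             accession=acc, name=name, value="")
            bin_el = etree.SubElement(bda, "binary")
            bin_el.text = encoded
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )


def _decode_binary_array(bda) -> np.ndarray:
    """Decode one <binaryDataArray>: base64, optional zlib, 32/64-bit float."""
    accessions = {cv.get("accession") for cv in bda.iter(f"{{{_MZML_NS}}}cvParam")}
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    binary = bda.find(f"{{{_MZML_NS}}}binary")
    raw = base64.b64decode(binary.text or "")
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path, individual_id: str) -> MassSpecRun:
    """Minimal mzML reader: MS1 centroid spectra, m/z + intensity arrays.

    Supports uncompressed and zlib-compressed 32/64-bit float arrays and
    scan start times in minutes or seconds; anything beyond that (MSn,
    vendor userParams, indexed wrappers) is ignored or unsupported.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise MSFormatError(f"{path}: not valid XML ({e})") from e
    scans = []
    for i, spec in enumerate(tree.iter(f"{{{_MZML_NS}}}spectrum")):
        params = {cv.get("accession"): cv.get("value")
                  for cv in spec.iter(f"{{{_MZML_NS}}}cvParam")}
        if params.get("MS:1000511", "1") not in ("1", ""):
            continue  # MSn spectra are out of scope
        rt = None
        for scan_el in spec.iter(f"{{{_MZML_NS}}}scan"):
            for cv in scan_el.iter(f"{{{_MZML_NS}}}cvParam"):
                if cv.get("accession") == "MS:1000016":
                    rt = float(cv.get("value"))
                    if cv.get("unitName") == "second":
                        rt /= 60.0
        if rt is None:
            raise MSFormatError(f"{path}: spectrum {i} has no scan start time")
        arrays = {}
        for bda in spec.iter(f"{{{_MZML_NS}}}binaryDataArray"):
            accs = {cv.get("accession")
                    for cv in bda.iter(f"{{{_MZML_NS}}}cvParam")}
            if "MS:1000514" in accs:
                arrays["mz"] = _decode_binary_array(bda)
            elif "MS:1000515" in accs:
                arrays["intensity"] = _decode_binary_array(bda)
        if set(arrays) != {"mz", "intensity"}:
            raise MSFormatError(
                f"{path}: spectrum {i} lacks m/z or intensity array"
            )
        try:
            scans.append(Scan(rt=rt, mz=arrays["mz"], intensity=arrays["intensity"]))
        except MSFormatError as e:
            raise MSFormatError(f"{path}: spectrum {i}: {e}") from e
    scans.sort(key=lambda s: s.rt)
    return MassSpecRun(individual_id=individual_id, scans=scans)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mzml":
        return "mzml"
    if suffix in (".tsv", ".txt", ".tab"):
        return "scan_table"
    raise MSFormatError(
        f"cannot infer format from {path.name!r}; pass format='mzml' or 'scan_table'"
    )


def read_run(path: str | Path, format: str | None = None,
             individual_id: str | None = None) -> MassSpecRun:
    """Read one acquisition from mzML or a TSV scan table.

    The individual id defaults to the filename stem. Scans are sorted by
    retention time; negative intensities and ragged scans are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise MSFormatError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    ind = individual_id if individual_id is not None else path.stem
    if fmt == "mzml":
        return _read_mzml(path, ind)
    if fmt == "scan_table":
        return _read_scan_table(path, ind)
    raise MSFormatError(f"unknown format {fmt!r}")


def write_run(run: MassSpecRun, path: str | Path, format: str | None = None) -> Path:
    """Write a run to mzML or scan-table TSV; refuses runs with no scans."""
    path = Path(path)
    if not run.scans:
        raise MSFormatError(
            f"refusing to serialize run {run.individual_id!r} with no scans"
        )
    fmt = format or _infer_format(path)
    if fmt == "mzml":
        _write_mzml(run, path)
    elif fmt == "scan_table":
        _write_scan_table(run, path)
    else:
        raise MSFormatError(f"unknown format {fmt!r}")
    return path
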