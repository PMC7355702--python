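"""Raw GC-MS scan I/O: mzML (MS1), long-format tables, labels and XIC traces.

A :class:`SampleRun` holds one sample's scan registers as parallel numpy
arrays of retention time (minutes), m/z (amu) and intensity (arbitrary
counts).  Input is assumed centroided; no peak picking is performed — the
downstream grid accumulator consumes raw registers directly.

The mzML support here is deliberately minimal: MS1 spectra with 32/64-bit
float arrays, uncompressed or zlib-compressed, which covers files produced
by :func:`write_mzml` and by common converters run with default MS1 export
settings.
"""

from __future__ import annotations

import base64
import csv
import io
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

__all__ = [
    "ScanRecord",
    "SampleRun",
    "read_mzml",
    "write_mzml",
    "read_long_table",
    "write_long_table",
    "read_labels",
    "write_labels",
    "extract_xic",
    "write_xic",
]

_MZML_NS = "http://psi.hupo.org/ms/mzml"

# PSI-MS controlled-vocabulary accessions understood by the reader.
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_UNIT_MINUTE = "UO:0000031"
_ACC_UNIT_SECOND = "UO:0000010"


class ScanRecord(NamedTuple):
    """One (retention time, m/z, intensity) register."""

    time: float  # minutes
    mz: float  # amu
    intensity: float  # arbitrary counts


@dataclass
class SampleRun:
    """All scan registers of one sample, with an optional binary class label.

    ``label`` follows the treated/non-treated convention: 1 = treated
    (class of interest), 0 = non-treated, ``None`` = unknown.
    """

    sample_id: str
    times: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        n = self.times.size
        if n == 0:
            raise ValueError(f"sample {self.sample_id!r} has no scan registers")
        if self.mz.size != n or self.intensity.size != n:
            raise ValueError("times, mz and intensity must have equal length")
        if np.any(self.times < 0):
            raise ValueError("retention times must be >= 0 minutes")
        if np.any(self.mz <= 0):
            raise ValueError("m/z values must be positive")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")

    def __len__(self) -> int:
        return self.times.size

    @property
    def records(self) -> Iterator[ScanRecord]:
        """Iterate registers in stored (scan) order."""
        for t, m, i in zip(self.times, self.mz, self.intensity):
            yield ScanRecord(float(t), float(m), float(i))

    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def scaled(self, factor: float) -> "SampleRun":
        """Return a copy with every intensity multiplied by ``factor``."""
        return SampleRun(
            self.sample_id, self.times.copy(), self.mz.copy(),
            self.intensity * factor, label=self.label,
        )


class MzmlParseError(ValueError):
    """Raised when an mzML file cannot be decoded into MS1 scan registers."""


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(text: str, accessions: set[str], length: int, path, scan_idx):
    try:
        raw = base64.b64decode(text.strip().encode(), validate=True)
    except Exception as exc:  # noqa: BLE001 - re-raised with context
        raise MzmlParseError(
            f"{path}: undecodable base64 binary in scan {scan_idx}: {exc}"
        ) from exc
    if _ACC_ZLIB in accessions:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in accessions else "<f8"
    arr = np.frombuffer(raw, dtype=dtype)
    if arr.size != length:
        raise MzmlParseError(
            f"{path}: scan {scan_idx} array length {arr.size} != "
            f"declared defaultArrayLength {length}"
        )
    return arr.astype(float)


def read_mzml(path, sample_id: str | None = None,
              label: int | None = None) -> SampleRun:
    """Read MS1 scans of an mzML file into a single :class:`SampleRun`.

    Retention times are converted to minutes; the time unit is taken from
    the scan-start-time unit accession, defaulting to seconds when absent.
    Scan order and within-scan peak order are preserved.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.removesuffix(".mzML").removesuffix(".mzml")
    times: list[np.ndarray] = []
    mzs: list[np.ndarray] = []
    intens: list[np.ndarray] = []
    scan_idx = -1
    try:
        context = ET.iterparse(str(path), events=("end",))
        for _, elem in context:
            if _local(elem.tag) != "spectrum":
                continue
            scan_idx += 1
            _parse_spectrum(elem, path, scan_idx, times, mzs, intens)
            elem.clear()
    except ET.ParseError as exc:
        raise MzmlParseError(
            f"{path}: malformed mzML near scan {scan_idx + 1}: {exc}"
        ) from exc
    if not times:
        raise MzmlParseError(f"{path}: no MS1 scans with peak data found")
    return SampleRun(
        sample_id,
        np.concatenate(times),
        np.concatenate(mzs),
        np.concatenate(intens),
        label=label,
    )


def _parse_spectrum(elem, path, scan_idx, times, mzs, intens) -> None:
    cv = {}  # accession -> (value, unit accession)
    for cvp in elem.iter():
        if _local(cvp.tag) == "cvParam":
            cv.setdefault(
                cvp.get("accession"),
                (cvp.get("value"), cvp.get("unitAccession")),
            )
    level = cv.get(_ACC_MS_LEVEL, ("1", None))[0]
    if level not in (None, "", "1"):
        return  # MS2+ ignored
    if _ACC_SCAN_START not in cv:
        raise MzmlParseError(f"{path}: scan {scan_idx} lacks a scan start time")
    value, unit = cv[_ACC_SCAN_START]
    t = float(value)
    if unit != _ACC_UNIT_MINUTE:
        # Default when the unit accession is absent or explicitly seconds.
        t /= 60.0
    n = int(elem.get("defaultArrayLength", "0"))
    mz_arr = int_arr = None
    for bda in elem.iter():
        if _local(bda.tag) != "binaryDataArray":
            continue
        accs = set()
        text = ""
        for child in bda:
            if _local(child.tag) == "cvParam":
                accs.add(child.get("accession"))
            elif _local(child.tag) == "binary":
                text = child.text or ""
        arr = _decode_binary(text, accs, n, path, scan_idx)
        if _ACC_MZ_ARRAY in accs:
            mz_arr = arr
        elif _ACC_INT_ARRAY in accs:
            int_arr = arr
    if mz_arr is None or int_arr is None:
        raise MzmlParseError(
            f"{path}: scan {scan_idx} is missing an m/z or intensity array"
        )
    if n:
        times.append(np.full(n, t))
        mzs.append(mz_arr)
        intens.append(int_arr)


def write_mzml(run: SampleRun, path) -> None:
    """Write a :class:`SampleRun` as a minimal centroid-MS1 mzML file.

    Registers are grouped into spectra by their exact retention time; 64-bit
    float arrays, uncompressed, scan start time in minutes.
    """
    path = Path(path)
    order = np.argsort(run.times, kind="stable")
    t_sorted = run.times[order]
    scan_times, starts = np.unique(t_sorted, return_index=True)
    bounds = list(starts) + [len(t_sorted)]

    def b64(a: np.ndarray) -> str:
        return base64.b64encode(np.asarray(a, dtype="<f8").tobytes()).decode()

    buf = io.StringIO()
    buf.write('<?xml version="1.0" encoding="utf-8"?>\n')
    buf.write(f'<mzML xmlns="{_MZML_NS}" version="1.1.0">\n')
    buf.write(
        '  <cvList count="2">\n'
        '    <cv id="MS" fullName="Proteomics Standards Initiative Mass '
        'Spectrometry Ontology" URI="https://raw.githubusercontent.com/'
        'HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>\n'
        '    <cv id="UO" fullName="Unit Ontology" '
        'URI="http://ontologies.berkeleybop.org/uo.obo"/>\n'
        "  </cvList>\n"
    )
    buf.write(f'  <run id={_xml_attr(run.sample_id)}>\n')
    buf.write(f'    <spectrumList count="{len(scan_times)}">\n')
    for s, (t, lo, hi) in enumerate(zip(scan_times, bounds[:-1], bounds[1:])):
        idx = order[lo:hi]
        mz_b = b64(run.mz[idx])
        in_b = b64(run.intensity[idx])
        buf.write(
            f'      <spectrum index="{s}" id="scan={s + 1}" '
            f'defaultArrayLength="{hi - lo}">\n'
            f'        <cvParam cvRef="MS" accession="{_ACC_MS_LEVEL}" '
            f'name="ms level" value="1"/>\n'
            f'        <cvParam cvRef="MS" accession="MS:1000127" '
            f'name="centroid spectrum" value=""/>\n'
            f"        <scanList count=\"1\">\n          <scan>\n"
            f'            <cvParam cvRef="MS" accession="{_ACC_SCAN_START}" '
            f'name="scan start time" value="{float(t)!r}" unitCvRef="UO" '
            f'unitAccession="{_ACC_UNIT_MINUTE}" unitName="minute"/>\n'
            f"          </scan>\n        </scanList>\n"
            f'        <binaryDataArrayList count="2">\n'
        )
        for acc, name, b in (
            (_ACC_MZ_ARRAY, "m/z array", mz_b),
            (_ACC_INT_ARRAY, "intensity array", in_b),
        ):
            buf.write(
                f'          <binaryDataArray encodedLength="{len(b)}">\n'
                f'            <cvParam cvRef="MS" accession="{_ACC_F64}" '
                f'name="64-bit float" value=""/>\n'
                f'            <cvParam cvRef="MS" accession="{_ACC_NOCOMP}" '
                f'name="no compression" value=""/>\n'
                f'            <cvParam cvRef="MS" accession="{acc}" '
                f'name="{name}" value=""/>\n'
                f"            <binary>{b}</binary>\n"
                f"          </binaryDataArray>\n"
            )
        buf.write("        </binaryDataArrayList>\n      </spectrum>\n")
    buf.write("    </spectrumList>\n  </run>\n</mzML>\n")
    path.write_text(buf.getvalue())


def _xml_attr(value: str) -> str:
    out = value.replace("&", "&amp;").replace("<", "&lt;").replace('"', "&quot;")
    return f'"{out}"'


_LONG_COLUMNS = ["sample_id", "time_min", "mz", "intensity"]


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    try:
        return csv.Sniffer().sniff(header, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_long_table(path, labels: dict[str, int] | None = None) -> list[SampleRun]:
    """Read a long-format delimited table into one :class:`SampleRun` per id.

    Expects a header with columns sample_id, time_min, mz, intensity;
    comma- or tab-delimited (auto-sniffed), decimal point only.  Rows are
    grouped by sample_id in order of first appearance; within-sample row
    order is preserved.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    if df.empty:
        return []
    numeric = {}
    for col in ("time_min", "mz", "intensity"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            # +2: one for the header row, one for 1-based numbering.
            raise ValueError(
                f"{path}: non-numeric {col} value {df[col].iloc[bad[0]]!r} "
                f"at line {bad[0] + 2}"
            )
        numeric[col] = vals.to_numpy()
    neg = np.nonzero(numeric["intensity"] < 0)[0]
    if len(neg):
        raise ValueError(
            f"{path}: negative intensity at line {neg[0] + 2}"
        )
    runs = []
    ids = df["sample_id"].to_numpy()
    for sid in pd.unique(ids):
        mask = ids == sid
        runs.append(
            SampleRun(
                str(sid),
                numeric["time_min"][mask],
                numeric["mz"][mask],
                numeric["intensity"][mask],
                label=None if labels is None else labels.get(str(sid)),
            )
        )
    return runs


def write_long_table(runs: Iterable[SampleRun], path, sep: str = ",") -> None:
    """Write runs as a long-format delimited table readable by
    :func:`read_long_table`."""
    frames = [
        pd.DataFrame(
            {
                "sample_id": run.sample_id,
                "time_min": run.times,
                "mz": run.mz,
                "intensity": run.intensity,
            }
        )
        for run in runs
    ]
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=_LONG_COLUMNS)
    out.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_labels(path) -> dict[str, int]:
    """Read a two-column (sample_id, label) table; labels must be 0 or 1."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    labels: dict[str, int] = {}
    for i, (sid, lab) in enumerate(zip(df["sample_id"], df["label"])):
        if lab not in ("0", "1"):
            raise ValueError(
                f"{path}: label must be 0 or 1, got {lab!r} at line {i + 2}"
            )
        if sid in labels:
            raise ValueError(f"{path}: duplicate sample_id {sid!r}")
        labels[str(sid)] = int(lab)
    return labels


def write_labels(runs: Iterable[SampleRun], path, sep: str = ",") -> None:
    rows = [(r.sample_id, r.label) for r in runs]
    for sid, lab in rows:
        if lab is None:
            raise ValueError(f"sample {sid!r} has no label to write")
    pd.DataFrame(rows, columns=["sample_id", "label"]).to_csv(
        path, sep=sep, index=False
    )


def extract_xic(
    run: SampleRun, ions: Sequence[int] | set[int], tolerance: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Summed extracted-ion chromatogram over the given fragment masses.

    For every scan time, sums the intensities of registers whose m/z falls
    in the half-open window [ion - tolerance, ion + tolerance) of any listed
    ion (half-open so a register on a window edge is never double-counted).

    Returns (times, intensities) with times strictly increasing; scans with
    no matching register contribute an explicit zero.
    """
    ions = sorted(set(int(i) for i in ions))
    if not ions:
        raise ValueError("ion set must be non-empty")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    mask = np.zeros(len(run), dtype=bool)
    for ion in ions:
        mask |= (run.mz >= ion - tolerance) & (run.mz < ion + tolerance)
    scan_times, inverse = np.unique(run.times, return_inverse=True)
    trace = np.bincount(
        inverse, weights=np.where(mask, run.intensity, 0.0),
        minlength=scan_times.size,
    )
    return scan_times, trace


def write_xic(times: np.ndarray, trace: np.ndarray, path, sep: str = ",") -> None:
    """Export an XIC as two-column delimited text (time_min, intensity)."""
    pd.DataFrame({"time_min": times, "intensity": trace}).to_csv(
        path, sep=sep, index=False, float_format="%.10g"
    )
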