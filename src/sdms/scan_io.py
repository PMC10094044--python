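"""Scan-level MS data containers and I/O.

Centroided scans are held as :class:`Scan`/:class:`ScanSeries`; a narrow m/z
window is pulled out of a series as an :class:`IntensitySeries`, the per-scan
intensity trace that all downstream fluctuation analysis operates on.

Two on-disk representations are supported: a fixed CSV dialect with header
``scan,time_min,mz,intensity`` (comma separator, dot decimal) and read-only
mzML restricted to the subset this toolkit needs (centroided spectra with a
scan start time).  Scan times are carried in minutes throughout.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .errors import ParseError, ValidationError

CSV_HEADER = ["scan", "time_min", "mz", "intensity"]


@dataclass(frozen=True)
class Scan:
    """One centroided scan: acquisition time plus (m/z, intensity) peaks.

    ``peaks`` are kept sorted ascending by m/z; intensities are counts >= 0.
    """

    index: int
    time: float  # minutes
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValidationError(f"scan index must be >= 0, got {self.index}")
        if self.time < 0:
            raise ValidationError(f"scan time must be >= 0, got {self.time}")
        pk = tuple(sorted((float(mz), float(i)) for mz, i in self.peaks))
        if any(i < 0 for _, i in pk):
            raise ValidationError("peak intensities must be >= 0")
        object.__setattr__(self, "peaks", pk)


@dataclass
class ScanSeries:
    """Ordered scans from one acquisition segment.

    ``metadata`` may carry the instrument mode (SRM / SIM / CID-MS/MS / full)
    and the collision energy in volts.
    """

    scans: list[Scan]
    segment_label: str = "segment"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.segment_label:
            raise ValidationError("segment_label must be non-empty")
        idx = [s.index for s in self.scans]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("scan indices must be strictly increasing")
        times = [s.time for s in self.scans]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError("scan times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.scans)


@dataclass(frozen=True)
class MeasurandWindow:
    """Closed m/z interval ``[center - tolerance, center + tolerance]``."""

    center_mz: float
    tolerance: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValidationError("window tolerance must be > 0")


@dataclass
class IntensitySeries:
    """Per-scan (time, intensity, matched m/z) trace for one measurand window.

    ``matched_mz`` holds NaN where a scan contributed no in-window peak
    (possible only under the ``zero`` no-match policy).
    """

    label: str
    times: np.ndarray
    intensities: np.ndarray
    matched_mz: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.matched_mz = np.asarray(self.matched_mz, dtype=float)
        if not (len(self.times) == len(self.intensities) == len(self.matched_mz)):
            raise ValidationError("times/intensities/matched_mz lengths differ")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def read_scan_table(path: str | Path, dialect: Literal["csv", "mzml"] = "csv") -> ScanSeries:
    """Read a :class:`ScanSeries` from CSV (dialect above) or centroided mzML.

    Rows sharing a scan index merge into one scan; peaks come back sorted.
    Non-monotone scan times raise a validation error.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "mzml":
        return _read_mzml(path)
    raise ValidationError(f"unknown dialect {dialect!r}")


def _read_csv(path: Path) -> ScanSeries:
    per_scan: dict[int, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if [h.strip() for h in header] != CSV_HEADER:
            raise ParseError(f"{path}: expected header {','.join(CSV_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                idx = int(row[0])
                t, mz, inten = float(row[1]), float(row[2]), float(row[3])
            except (ValueError, IndexError):
                raise ParseError(f"{path}: malformed row at line {lineno}") from None
            entry = per_scan.setdefault(idx, {"time": t, "peaks": []})
            entry["peaks"].append((mz, inten))
    scans = [
        Scan(index=i, time=per_scan[i]["time"], peaks=tuple(per_scan[i]["peaks"]))
        for i in sorted(per_scan)
    ]
    return ScanSeries(scans=scans, segment_label=path.stem)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(elem) -> np.ndarray:
    """Decode one <binaryDataArray>: 32/64-bit floats, plain or zlib."""
    import base64
    import zlib

    dtype = "<f8"
    compressed = False
    payload = b""
    for child in elem.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":  # 32-bit float
                dtype = "<f4"
            elif acc == "MS:1000523":  # 64-bit float
                dtype = "<f8"
            elif acc == "MS:1000574":  # zlib compression
                compressed = True
        elif name == "binary" and child.text:
            payload = base64.b64decode(child.text.strip())
    if compressed:
        payload = zlib.decompress(payload)
    return np.frombuffer(payload, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> ScanSeries:
    """Minimal mzML subset reader: centroided spectra with scan start time.

    Covers the structures this toolkit needs — 32/64-bit float m/z and
    intensity arrays, plain or zlib-compressed, scan start time in minutes
    or seconds.  Namespace-agnostic so both 1.0 and 1.1 documents parse.
    """
    import xml.etree.ElementTree as ET

    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ParseError(f"{path}: not well-formed mzML ({exc})") from None
    scans = []
    for i, spec in enumerate(
        e for e in tree.getroot().iter() if _local(e.tag) == "spectrum"
    ):
        t_min = 0.0
        for cv in spec.iter():
            if _local(cv.tag) == "cvParam" and cv.get("accession") == "MS:1000016":
                t_min = float(cv.get("value", "0"))
                unit = (cv.get("unitName") or "minute").lower()
                if unit.startswith("second"):
                    t_min /= 60.0
                break
        mzs = ints = None
        for arr in (e for e in spec.iter() if _local(e.tag) == "binaryDataArray"):
            accs = {
                c.get("accession") for c in arr.iter() if _local(c.tag) == "cvParam"
            }
            data = _decode_binary_array(arr)
            if "MS:1000514" in accs:  # m/z array
                mzs = data
            elif "MS:1000515" in accs:  # intensity array
                ints = data
        if mzs is None or ints is None:
            raise ParseError(f"{path}: spectrum {i} lacks m/z or intensity array")
        if mzs.size != ints.size:
            raise ParseError(f"{path}: spectrum {i} array length mismatch")
        scans.append(Scan(index=i, time=t_min, peaks=tuple(zip(mzs, ints))))
    return ScanSeries(scans=scans, segment_label=path.stem)


def write_scan_table(series: ScanSeries, path: str | Path) -> Path:
    """Write the CSV dialect; rows ordered by scan index then m/z."""
    path = Path(path)
    try:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_HEADER)
            for scan in series.scans:
                for mz, inten in scan.peaks:
                    writer.writerow(
                        [scan.index, repr(float(scan.time)), repr(float(mz)), repr(float(inten))]
                    )
    except OSError as exc:
        raise SdmsIOError(f"cannot write {path}: {exc}") from exc
    return path


class SdmsIOError(ValidationError):
    """Unwritable or unreadable path."""


def extract_window(
    series: ScanSeries,
    window: MeasurandWindow,
    no_match_policy: Literal["zero", "skip"] = "zero",
) -> IntensitySeries:
    """Pull the per-scan trace of the most intense in-window peak.

    For each scan the most intense peak with ``|mz - center| <= tolerance``
    is selected.  Ties on intensity go to the peak closer to the window
    center, then to the lower m/z, so extraction is deterministic and
    independent of peak order.  Unmatched scans contribute intensity 0 (and a
    NaN matched m/z) under policy ``zero`` and are dropped under ``skip``.
    """
    if len(series) == 0:
        raise ValidationError("cannot extract from an empty ScanSeries")
    if no_match_policy not in ("zero", "skip"):
        raise ValidationError(f"unknown no_match_policy {no_match_policy!r}")
    lo = window.center_mz - window.tolerance
    hi = window.center_mz + window.tolerance
    times, intens, mzs = [], [], []
    for scan in series.scans:
        best: tuple[float, float, float] | None = None  # (-intensity, dist, mz)
        for mz, inten in scan.peaks:
            if lo <= mz <= hi:
                key = (-inten, abs(mz - window.center_mz), mz)
                if best is None or key < best:
                    best = key
        if best is not None:
            times.append(scan.time)
            intens.append(-best[0])
            mzs.append(best[2])
        elif no_match_policy == "zero":
            times.append(scan.time)
            intens.append(0.0)
            mzs.append(math.nan)
    # equal scan times would break the strictly-increasing invariant; nudge is
    # not attempted — the caller's acquisition grid is authoritative
    label = window.label or f"mz{window.center_mz:g}"
    return IntensitySeries(
        label=label,
        times=np.asarray(times),
        intensities=np.asarray(intens),
        matched_mz=np.asarray(mzs),
    )
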