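"""Record, annotation and report I/O.

Containers
----------
:class:`MultichannelRecord`
    Sampled multichannel abdominal ECG (aECG) in millivolts.
:class:`AnnotationSet`
    Ordered R-peak sample indices (reference or detected beats).
:class:`EvaluationReport`
    Per-window and aggregate TP/FP/FN counts with Se/PPV/F1 percentages.

Formats
-------
* CSV: one column per channel, header row of channel names, full float
  precision. The sampling rate travels in a JSON sidecar (``<stem>.json``)
  or is passed explicitly.
* WFDB: a minimal hand-written subset of the PhysioNet signal format
  (``.hea`` header + format-16 multiplexed ``.dat``) and of the MIT
  annotation format (2-byte words, SKIP escapes for long intervals).
  Amplitudes are quantized at 1/gain mV on this path.
* Reports: JSON (schema-versioned) or flat CSV.

All sample indices are 0-based throughout the package.
"""

from __future__ import annotations

import csv
import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, ValidationError

REPORT_SCHEMA_VERSION = 1

# MIT annotation codes used by the minimal writer/reader.
_ANN_NORMAL = 1
_ANN_SKIP = 59
_ANN_MAX_INC = 1023  # largest time increment in a single annotation word


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MultichannelRecord:
    """Multichannel ECG: ``samples[n, c]`` in mV at sampling rate ``fs`` Hz."""

    samples: np.ndarray
    fs: float
    channel_names: list[str]
    record_id: str = "record"

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2 or self.samples.shape[0] < 1 or self.samples.shape[1] < 1:
            raise ValidationError("record must be a non-empty [n_samples x n_channels] matrix")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.samples.shape[1]:
            raise ValidationError("channel_names length must match channel count")
        bad = ~np.isfinite(self.samples)
        if bad.any():
            ch = int(np.argwhere(bad.any(axis=0))[0][0])
            raise ValidationError(
                f"non-finite samples in channel {self.channel_names[ch]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    def channel(self, idx: int) -> np.ndarray:
        return self.samples[:, idx]

    def subset(self, indices) -> "MultichannelRecord":
        """New record restricted to ``indices``; fs and values preserved."""
        indices = list(indices)
        return MultichannelRecord(
            samples=self.samples[:, indices].copy(),
            fs=self.fs,
            channel_names=[self.channel_names[i] for i in indices],
            record_id=self.record_id,
        )


@dataclass
class AnnotationSet:
    """Strictly increasing R-peak sample positions at rate ``fs``."""

    peak_indices: np.ndarray
    fs: float
    label: str = "reference"

    def __post_init__(self):
        idx = np.asarray(self.peak_indices, dtype=np.int64).ravel()
        if idx.size and idx.min() < 0:
            raise ValidationError("annotation indices must be non-negative")
        uniq = np.unique(idx)
        if uniq.size != idx.size:
            warnings.warn("duplicate annotation indices removed", stacklevel=2)
        self.peak_indices = uniq
        if self.fs <= 0:
            raise ValidationError("annotation fs must be positive")

    def __len__(self) -> int:
        return int(self.peak_indices.size)

    def times_s(self) -> np.ndarray:
        return self.peak_indices / self.fs


@dataclass
class EvaluationReport:
    """TP/FP/FN counts per window plus micro-averaged aggregate metrics."""

    windows: list[dict] = field(default_factory=list)
    tp: int = 0
    fp: int = 0
    fn: int = 0
    se: float | None = None
    ppv: float | None = None
    f1: float | None = None
    parameters: dict = field(default_factory=dict)
    record_id: str = ""

    def __post_init__(self):
        for name in ("tp", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValidationError(f"count {name} must be a non-negative integer")
        for name in ("se", "ppv", "f1"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValidationError(f"{name} must lie in [0, 100], got {v}")

    def to_dict(self) -> dict:
        def r2(x):
            return None if x is None else round(float(x), 2)

        return {
            "schema": REPORT_SCHEMA_VERSION,
            "record_id": self.record_id,
            "tp": int(self.tp),
            "fp": int(self.fp),
            "fn": int(self.fn),
            "se": r2(self.se),
            "ppv": r2(self.ppv),
            "f1": r2(self.f1),
            "parameters": self.parameters,
            "windows": self.windows,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(
            windows=list(d.get("windows", [])),
            tp=int(d.get("tp", 0)),
            fp=int(d.get("fp", 0)),
            fn=int(d.get("fn", 0)),
            se=d.get("se"),
            ppv=d.get("ppv"),
            f1=d.get("f1"),
            parameters=dict(d.get("parameters", {})),
            record_id=d.get("record_id", ""),
        )


# ---------------------------------------------------------------------------
# CSV records
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_record_csv(path: Path, fs: float | None) -> MultichannelRecord:
    sidecar = _sidecar_path(path)
    record_id = path.stem
    if fs is None:
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            fs = meta.get("fs")
            record_id = meta.get("record_id", record_id)
        if fs is None:
            raise ConfigError(
                f"sampling rate for CSV record {path} not given and no sidecar found"
            )
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        rows = [[float(v) for v in row] for row in reader if row]
    if not rows:
        raise ValidationError(f"CSV record {path} contains no samples")
    samples = np.asarray(rows, dtype=float)
    return MultichannelRecord(samples, float(fs), [h.strip() for h in header], record_id)


def _write_record_csv(record: MultichannelRecord, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(record.channel_names)
        for row in record.samples:
            writer.writerow([repr(float(v)) for v in row])
    _sidecar_path(path).write_text(
        json.dumps({"fs": record.fs, "record_id": record.record_id}, indent=2)
    )


# ---------------------------------------------------------------------------
# Minimal WFDB (.hea + format-16 .dat)
# ---------------------------------------------------------------------------

_WFDB_GAIN = 1000.0  # adu per mV; quantization step 1e-3 mV


def _write_record_wfdb(record: MultichannelRecord, hea_path: Path) -> None:
    name = hea_path.stem
    dat_name = name + ".dat"
    adc = np.round(record.samples * _WFDB_GAIN)
    if np.abs(adc).max(initial=0) > 32767:
        raise ValidationError("sample amplitude exceeds int16 range at WFDB gain")
    adc = adc.astype("<i2")
    lines = [f"{name} {record.n_channels} {record.fs:g} {record.n_samples}"]
    for c in range(record.n_channels):
        lines.append(
            f"{dat_name} 16 {_WFDB_GAIN:g}(0)/mV 16 0 {int(adc[0, c])} 0 0 "
            f"{record.channel_names[c]}"
        )
    hea_path.write_text("\n".join(lines) + "\n")
    (hea_path.parent / dat_name).write_bytes(adc.reshape(-1).tobytes())


def _read_record_wfdb(hea_path: Path) -> MultichannelRecord:
    lines = [
        ln for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    name, n_sig, fs = head[0], int(head[1]), float(head[2])
    n_samples = int(head[3]) if len(head) > 3 else None
    gains, baselines, names, dat_files, fmts = [], [], [], [], []
    for ln in lines[1:1 + n_sig]:
        parts = ln.split()
        dat_files.append(parts[0])
        fmts.append(parts[1])
        gain_spec = parts[2] if len(parts) > 2 else "200"
        gain_str = gain_spec.split("/")[0]
        if "(" in gain_str:
            g, b = gain_str.split("(")
            gains.append(float(g) if float(g) != 0 else 200.0)
            baselines.append(float(b.rstrip(")")))
        else:
            gains.append(float(gain_str) if float(gain_str) != 0 else 200.0)
            baselines.append(0.0)
        names.append(parts[-1] if len(parts) > 3 else f"ch{len(names)}")
    if any(f != "16" for f in fmts):
        raise ConfigError("only WFDB format 16 is supported")
    if len(set(dat_files)) != 1:
        raise ConfigError("only single-.dat WFDB records are supported")
    raw = np.frombuffer((hea_path.parent / dat_files[0]).read_bytes(), dtype="<i2")
    if n_samples is None:
        n_samples = raw.size // n_sig
    adc = raw[: n_samples * n_sig].reshape(n_samples, n_sig).astype(float)
    samples = (adc - np.asarray(baselines)) / np.asarray(gains)
    return MultichannelRecord(samples, fs, names, record_id=name)


# ---------------------------------------------------------------------------
# Public record API
# ---------------------------------------------------------------------------

def read_record(path, format: str = "csv", fs: float | None = None) -> MultichannelRecord:
    """Read a multichannel ECG record.

    Parameters
    ----------
    path : path-like
        CSV file or WFDB ``.hea`` header.
    format : {"csv", "wfdb"}
    fs : float, optional
        Required for CSV records without a JSON sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"record file not found: {path}")
    if format == "csv":
        return _read_record_csv(path, fs)
    if format == "wfdb":
        return _read_record_wfdb(path)
    raise ConfigError(f"unknown record format {format!r}")


def write_record(record: MultichannelRecord, path, format: str = "csv") -> None:
    path = Path(path)
    if format == "csv":
        _write_record_csv(record, path)
    elif format == "wfdb":
        _write_record_wfdb(record, path)
    else:
        raise ConfigError(f"unknown record format {format!r}")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def _read_annotations_text(path: Path) -> np.ndarray:
    tokens = path.read_text().replace(",", " ").split()
    vals = []
    for t in tokens:
        v = int(t)
        if v < 0:
            raise ValidationError(f"negative annotation index {v} in {path}")
        vals.append(v)
    return np.asarray(vals, dtype=np.int64)


def _write_annotations_wfdb(indices: np.ndarray, path: Path) -> None:
    words = bytearray()
    t = 0
    for idx in indices:
        inc = int(idx) - t
        if inc > _ANN_MAX_INC:
            words += struct.pack("<H", _ANN_SKIP << 10)
            words += struct.pack("<H", (inc >> 16) & 0xFFFF)
            words += struct.pack("<H", inc & 0xFFFF)
            inc = 0
            t = int(idx)
            words += struct.pack("<H", (_ANN_NORMAL << 10) | inc)
        else:
            words += struct.pack("<H", (_ANN_NORMAL << 10) | inc)
            t = int(idx)
    words += struct.pack("<H", 0)  # EOF
    path.write_bytes(bytes(words))


def _read_annotations_wfdb(path: Path) -> np.ndarray:
    data = path.read_bytes()
    out, t, i = [], 0, 0
    while i + 1 < len(data):
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        code, inc = word >> 10, word & 0x3FF
        if code == 0 and inc == 0:
            break
        if code == _ANN_SKIP:
            hi, lo = struct.unpack_from("<HH", data, i)
            i += 4
            t += (hi << 16) | lo
            continue
        t += inc
        out.append(t)
    return np.asarray(out, dtype=np.int64)


def read_annotations(path, format: str = "text", fs: float = 1.0,
                     label: str = "reference") -> AnnotationSet:
    """Read beat annotations from a text list or a WFDB annotation file."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"annotation file not found: {path}")
    if format == "text":
        idx = _read_annotations_text(path)
    elif format == "wfdb_ann":
        idx = _read_annotations_wfdb(path)
    else:
        raise ConfigError(f"unknown annotation format {format!r}")
    return AnnotationSet(idx, fs=fs, label=label)


def write_annotations(ann: AnnotationSet, path, format: str = "text") -> None:
    path = Path(path)
    if format == "text":
        path.write_text("\n".join(str(int(i)) for i in ann.peak_indices) + "\n")
    elif format == "wfdb_ann":
        _write_annotations_wfdb(ann.peak_indices, path)
    else:
        raise ConfigError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(report: EvaluationReport, path, format: str = "json") -> None:
    """Serialize an evaluation report (percentages rounded to 2 decimals)."""
    path = Path(path)
    d = report.to_dict()
    if format == "json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    elif format == "csv":
        cols = ["record_id", "tp", "fp", "fn", "se", "ppv", "f1"]
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["schema"] + cols)
            writer.writerow([REPORT_SCHEMA_VERSION] + [d[c] for c in cols])
    else:
        raise ConfigError(f"unknown report format {format!r}")


def read_report(path, format: str = "json") -> EvaluationReport:
    path = Path(path)
    if format == "json":
        return EvaluationReport.from_dict(json.loads(path.read_text()))
    if format == "csv":
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            row = next(reader)
        d = dict(zip(header, row))
        return EvaluationReport(
            tp=int(d["tp"]), fp=int(d["fp"]), fn=int(d["fn"]),
            se=None if d["se"] in ("", "None") else float(d["se"]),
            ppv=None if d["ppv"] in ("", "None") else float(d["ppv"]),
            f1=None if d["f1"] in ("", "None") else float(d["f1"]),
            record_id=d.get("record_id", ""),
        )
    raise ConfigError(f"unknown report format {format!r}")
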