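"""Delimited-text I/O for traces, correlation curves, histograms and bleach series.

Every file starts with a header block of ``# key = value`` lines
(including a ``ffskit_type`` tag) followed by whitespace-delimited
columns.  Floats are written with 12 significant digits; write-then-read
round-trips counts exactly and floats to that precision.
"""

from __future__ import annotations

import os
from typing import TextIO

import numpy as np

from .anisotropy import BleachSeries
from .fcs import CorrelationCurve
from .pch import PCHistogram
from .simulate import PhotonTrace

__all__ = [
    "ParseError",
    "write_trace",
    "read_trace",
    "write_curve",
    "read_curve",
    "write_histogram",
    "read_histogram",
    "write_bleach_series",
    "read_bleach_series",
    "roundtrip",
]

_FLOAT_FMT = "%.12g"


class ParseError(ValueError):
    """Malformed file; carries the offending path and line number."""

    def __init__(self, path: str, line_no: int, message: str) -> None:
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = path
        self.line_no = line_no


def _write_header(fh: TextIO, ftype: str, meta: dict) -> None:
    fh.write(f"# ffskit_type = {ftype}\n")
    for key, val in meta.items():
        if isinstance(val, float):
            val = _FLOAT_FMT % val
        fh.write(f"# {key} = {val}\n")


def _read_file(path: str, expected_type: str, n_cols: tuple[int, ...]):
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    width: int | None = None
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            fields = line.split()
            if width is None:
                if len(fields) not in n_cols:
                    raise ParseError(
                        path, line_no,
                        f"expected {' or '.join(map(str, n_cols))} columns, "
                        f"got {len(fields)}",
                    )
                width = len(fields)
            elif len(fields) != width:
                raise ParseError(
                    path, line_no,
                    f"inconsistent column count: expected {width}, got {len(fields)}",
                )
            for f in fields:
                try:
                    float(f)
                except ValueError:
                    raise ParseError(path, line_no, f"non-numeric field {f!r}") from None
            rows.append(fields)
    ftype = meta.pop("ffskit_type", None)
    if ftype != expected_type:
        raise ParseError(
            path, 1, f"expected ffskit_type = {expected_type}, found {ftype}"
        )
    if not rows:
        raise ParseError(path, 1, "file contains no data rows")
    return meta, np.array(rows, dtype=object)


def _require_meta(meta: dict, key: str, path: str) -> str:
    if key not in meta:
        raise ParseError(path, 1, f"missing required header key {key!r}")
    return meta[key]


# -- photon traces -----------------------------------------------------------

def write_trace(trace: PhotonTrace, path: str) -> None:
    with open(path, "w") as fh:
        meta = {"bin_time_s": float(trace.bin_time)}
        for key in ("seed", "config_hash"):
            if key in trace.metadata:
                meta[key] = trace.metadata[key]
        _write_header(fh, "photon_trace", meta)
        fh.write("# columns: bin_index counts\n")
        for i, c in enumerate(trace.counts):
            fh.write(f"{i} {c}\n")


def read_trace(path: str) -> PhotonTrace:
    meta, rows = _read_file(path, "photon_trace", (2,))
    bin_time = float(_require_meta(meta, "bin_time_s", path))
    idx = rows[:, 0].astype(int)
    counts = rows[:, 1].astype(int)
    if not np.array_equal(idx, np.arange(idx.size)):
        raise ParseError(path, 1, "bin_index column must run 0..n-1 contiguously")
    md: dict = {}
    if "seed" in meta:
        md["seed"] = int(meta["seed"])
    if "config_hash" in meta:
        md["config_hash"] = meta["config_hash"]
    return PhotonTrace(counts=counts, bin_time=bin_time, metadata=md)


# -- correlation curves ------------------------------------------------------

def write_curve(curve: CorrelationCurve, path: str) -> None:
    with open(path, "w") as fh:
        meta = {
            k: curve.source[k]
            for k in ("estimator", "bin_time_s", "duration_s")
            if k in curve.source
        }
        _write_header(fh, "correlation_curve", meta)
        has_sem = curve.sem is not None
        fh.write("# columns: lag_s G" + (" sem" if has_sem else "") + "\n")
        for i in range(curve.lags.size):
            row = [_FLOAT_FMT % curve.lags[i], _FLOAT_FMT % curve.G[i]]
            if has_sem:
                row.append(_FLOAT_FMT % curve.sem[i])
            fh.write(" ".join(row) + "\n")


def read_curve(path: str) -> CorrelationCurve:
    meta, rows = _read_file(path, "correlation_curve", (2, 3))
    source: dict = {}
    for key in ("bin_time_s", "duration_s"):
        if key in meta:
            source[key] = float(meta[key])
    if "estimator" in meta:
        source["estimator"] = meta["estimator"]
    sem = rows[:, 2].astype(float) if rows.shape[1] == 3 else None
    return CorrelationCurve(
        lags=rows[:, 0].astype(float), G=rows[:, 1].astype(float),
        sem=sem, source=source,
    )


# -- photon counting histograms ---------------------------------------------

def write_histogram(hist: PCHistogram, path: str) -> None:
    with open(path, "w") as fh:
        _write_header(fh, "pch_histogram", {"bin_time_s": float(hist.bin_time)})
        fh.write("# columns: count frequency\n")
        for k, f in zip(hist.counts_axis, hist.frequency):
            fh.write(f"{k} {f}\n")


def read_histogram(path: str) -> PCHistogram:
    meta, rows = _read_file(path, "pch_histogram", (2,))
    bin_time = float(_require_meta(meta, "bin_time_s", path))
    return PCHistogram(
        counts_axis=rows[:, 0].astype(int),
        frequency=rows[:, 1].astype(int),
        bin_time=bin_time,
    )


# -- photobleaching series ---------------------------------------------------

def write_bleach_series(series: BleachSeries, path: str) -> None:
    with open(path, "w") as fh:
        _write_header(fh, "bleach_series", {})
        has_sem = series.sem is not None
        fh.write(
            "# columns: bleached_fraction anisotropy" + (" sem" if has_sem else "") + "\n"
        )
        for i in range(series.n_points):
            row = [_FLOAT_FMT % series.b[i], _FLOAT_FMT % series.r_obs[i]]
            if has_sem:
                row.append(_FLOAT_FMT % series.sem[i])
            fh.write(" ".join(row) + "\n")


def read_bleach_series(path: str) -> BleachSeries:
    _, rows = _read_file(path, "bleach_series", (2, 3))
    sem = rows[:, 2].astype(float) if rows.shape[1] == 3 else None
    return BleachSeries(
        b=rows[:, 0].astype(float), r_obs=rows[:, 1].astype(float), sem=sem
    )


_WRITERS = {
    PhotonTrace: (write_trace, read_trace),
    CorrelationCurve: (write_curve, read_curve),
    PCHistogram: (write_histogram, read_histogram),
    BleachSeries: (write_bleach_series, read_bleach_series),
}


def roundtrip(obj, path: str | None = None):
    """Write an object to disk and read it back (contract check helper)."""
    import tempfile

    writer, reader = _WRITERS[type(obj)]
    if path is None:
        fd, path = tempfile.mkstemp(suffix=".tsv")
        os.close(fd)
        try:
            writer(obj, path)
            return reader(path)
        finally:
            os.unlink(path)
    writer(obj, path)
    return reader(path)
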