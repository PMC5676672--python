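"""Fast-time x slow-time echo matrix container and its on-disk formats.

An impulse-radar record is a two-dimensional grid: rows are fast-time
samples (intra-pulse delay, equivalently range via r = c*tau/2), columns
are slow-time samples (pulse-to-pulse, carrying the breathing modulation).

Two round-trip-exact formats are provided:

* CSV — human-readable; ``#``-prefixed metadata header, then one row per
  range bin whose first column is the bin's range in metres.  Values are
  written with 17 significant digits so float64 round-trips exactly.
* binary — raw little-endian float64 samples plus a small JSON sidecar
  (``<path>.json``) carrying shape, dtype and axis metadata; bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import MatrixFormatError

SPEED_OF_LIGHT_M_S = 3.0e8

_CSV_MAGIC = "bioradar-matrix"
_REQUIRED_META = ("fast_dt_ns", "slow_fs_hz")


@dataclass
class EchoMatrix:
    """M x N real-valued echo grid with axis metadata.

    Parameters
    ----------
    data
        Array of shape ``(n_range, n_slow)``; row *m* is the slow-time
        signal observed at fast-time delay ``m * fast_dt_ns``.
    fast_dt_ns
        Fast-time sample step (two-way delay) in nanoseconds.  After range
        accumulation this is the mean step of the (near-uniform) binned axis.
    slow_fs_hz
        Slow-time sampling rate in Hz.  For lag-domain matrices produced by
        autocorrelation the columns are lags spaced ``1/slow_fs_hz`` apart.
    range_axis_m
        Strictly increasing per-row range in metres, ``r = c*tau/2``.
    """

    data: np.ndarray
    fast_dt_ns: float
    slow_fs_hz: float
    range_axis_m: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise MatrixFormatError(f"data must be 2-D, got ndim={self.data.ndim}")
        if self.fast_dt_ns <= 0 or self.slow_fs_hz <= 0:
            raise MatrixFormatError("fast_dt_ns and slow_fs_hz must be positive")
        if self.range_axis_m is None:
            tau_ns = np.arange(self.data.shape[0]) * self.fast_dt_ns
            self.range_axis_m = SPEED_OF_LIGHT_M_S * (tau_ns * 1e-9) / 2.0
        self.range_axis_m = np.asarray(self.range_axis_m, dtype=np.float64)
        if self.range_axis_m.shape != (self.data.shape[0],):
            raise MatrixFormatError(
                f"range axis length {self.range_axis_m.shape} does not match "
                f"{self.data.shape[0]} rows"
            )
        if self.data.shape[0] > 1 and np.any(np.diff(self.range_axis_m) <= 0):
            raise MatrixFormatError("range_axis_m must be strictly increasing")

    @property
    def n_range(self) -> int:
        return self.data.shape[0]

    @property
    def n_slow(self) -> int:
        return self.data.shape[1]

    @property
    def slow_time_s(self) -> np.ndarray:
        return np.arange(self.n_slow) / self.slow_fs_hz

    def with_data(self, data: np.ndarray, **changes) -> "EchoMatrix":
        """Copy of this matrix with new samples (and optional metadata)."""
        return replace(self, data=np.asarray(data, dtype=np.float64), **changes)

    def nearest_bin(self, range_m: float) -> int:
        """Index of the range bin whose centre is closest to ``range_m``."""
        return int(np.argmin(np.abs(self.range_axis_m - range_m)))


def write_matrix(m: EchoMatrix, path: str | Path, fmt: str | None = None) -> None:
    """Write an :class:`EchoMatrix` as ``csv`` or ``binary`` (+ JSON sidecar).

    ``fmt=None`` infers the format from the suffix (``.csv`` -> csv,
    anything else -> binary).
    """
    path = Path(path)
    fmt = _infer_fmt(path, fmt)
    if fmt == "csv":
        _write_csv(m, path)
    elif fmt == "binary":
        _write_binary(m, path)
    else:
        raise MatrixFormatError(f"unknown matrix format {fmt!r}")


def read_matrix(path: str | Path, fmt: str | None = None) -> EchoMatrix:
    """Read an :class:`EchoMatrix` written by :func:`write_matrix`."""
    path = Path(path)
    fmt = _infer_fmt(path, fmt)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "binary":
        return _read_binary(path)
    raise MatrixFormatError(f"unknown matrix format {fmt!r}")


def _infer_fmt(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "csv" if path.suffix.lower() == ".csv" else "binary"


def _write_csv(m: EchoMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_CSV_MAGIC}\n")
        fh.write(f"# fast_dt_ns={m.fast_dt_ns!r}\n")
        fh.write(f"# slow_fs_hz={m.slow_fs_hz!r}\n")
        fh.write(f"# shape={m.n_range}x{m.n_slow}\n")
        body = np.column_stack([m.range_axis_m, m.data])
        np.savetxt(fh, body, delimiter=",", fmt="%.17g")


def _read_csv(path: Path) -> EchoMatrix:
    meta: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            stripped = line[1:].strip()
            if "=" in stripped:
                key, _, value = stripped.partition("=")
                meta[key.strip()] = value.strip()
    for key in _REQUIRED_META:
        if key not in meta:
            raise MatrixFormatError(f"CSV header missing metadata key {key!r}")
    body = np.loadtxt(path, delimiter=",", skiprows=n_header, ndmin=2)
    if body.shape[1] < 2:
        raise MatrixFormatError("CSV body must have a range column plus data")
    if "shape" in meta:
        rows, _, cols = meta["shape"].partition("x")
        expected = (int(rows), int(cols) + 1)
        if body.shape != expected:
            raise MatrixFormatError(
                f"CSV body shape {body.shape} does not match metadata "
                f"shape {meta['shape']}"
            )
    return EchoMatrix(
        data=body[:, 1:],
        fast_dt_ns=float(meta["fast_dt_ns"]),
        slow_fs_hz=float(meta["slow_fs_hz"]),
        range_axis_m=body[:, 0],
    )


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _write_binary(m: EchoMatrix, path: Path) -> None:
    m.data.astype("<f8").tofile(path)
    meta = {
        "format": _CSV_MAGIC,
        "dtype": "<f8",
        "shape": [m.n_range, m.n_slow],
        "fast_dt_ns": m.fast_dt_ns,
        "slow_fs_hz": m.slow_fs_hz,
        "range_axis_m": m.range_axis_m.tolist(),
    }
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh)


def _read_binary(path: Path) -> EchoMatrix:
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise MatrixFormatError(f"missing JSON sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in _REQUIRED_META + ("shape", "dtype"):
        if key not in meta:
            raise MatrixFormatError(f"sidecar missing metadata key {key!r}")
    raw = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
    shape = tuple(meta["shape"])
    if raw.size != shape[0] * shape[1]:
        raise MatrixFormatError(
            f"binary payload has {raw.size} samples, metadata shape {shape} "
            f"needs {shape[0] * shape[1]}"
        )
    return EchoMatrix(
        data=raw.reshape(shape),
        fast_dt_ns=float(meta["fast_dt_ns"]),
        slow_fs_hz=float(meta["slow_fs_hz"]),
        range_axis_m=np.asarray(meta["range_axis_m"], dtype=np.float64),
    )
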