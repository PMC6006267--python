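"""Reading and writing DVS address-event streams.

Two dialects are supported:

``jaer``
    The binary AER-DAT format written by jAER for DVS128 retinas.
    Version 1 records are a big-endian 16-bit address followed by a
    32-bit timestamp; version 2 files start with a ``#!AER-DAT2.0``
    header line and use 32-bit addresses.  DVS128 address bit fields:
    bit 0 = polarity (1 -> +1), bits 1-7 = x, bits 8-14 = y.

``csv``
    A plain-text dialect with header ``timestamp_us,x,y,polarity`` and
    one event per line.

Also provides a phase-histogram filter for periodic timestamp
artifacts such as the harmonic an LCD monitor imprints on screen
recordings.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .events import EventStream, ValidationError

__all__ = ["AERParseError", "read_events", "write_events", "filter_periodic_artifact"]

logger = logging.getLogger(__name__)

_V2_MAGIC = b"#!AER-DAT2.0"
_V1_MAGIC = b"#!AER-DAT1.0"

#: DVS128 address bit layout (16 low bits; identical in the 32-bit v2 word).
_POL_BIT = 0
_X_SHIFT, _X_MASK = 1, 0x7F
_Y_SHIFT, _Y_MASK = 8, 0x7F


class AERParseError(ValueError):
    """Malformed AER file; the message names the offending byte or line."""


def _pack_addresses(stream: EventStream) -> np.ndarray:
    pol_bit = (stream.polarity > 0).astype(np.uint32)
    return (
        (stream.y.astype(np.uint32) & _Y_MASK) << _Y_SHIFT
        | (stream.x.astype(np.uint32) & _X_MASK) << _X_SHIFT
        | pol_bit << _POL_BIT
    )


def _unpack_addresses(addr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = (addr >> _X_SHIFT) & _X_MASK
    y = (addr >> _Y_SHIFT) & _Y_MASK
    pol = np.where((addr >> _POL_BIT) & 1, 1, -1)
    return x.astype(np.int64), y.astype(np.int64), pol.astype(np.int64)


def _read_jaer(path: Path, width: int, height: int) -> EventStream:
    raw = path.read_bytes()
    offset = 0
    version = 1
    if raw.startswith(_V2_MAGIC):
        version = 2
    elif raw.startswith(_V1_MAGIC):
        version = 1
    elif raw.startswith(b"#!"):
        raise AERParseError(f"{path}: unknown AER-DAT header at byte 0")
    # Skip '#'-prefixed comment lines (each terminated by \n).
    while offset < len(raw) and raw[offset : offset + 1] == b"#":
        nl = raw.find(b"\n", offset)
        if nl < 0:
            raise AERParseError(f"{path}: unterminated header line at byte {offset}")
        offset = nl + 1
    body = raw[offset:]
    if not raw.startswith(b"#"):
        # Headerless file: infer the record size from divisibility.
        if len(body) % 6 == 0:
            version = 1
        elif len(body) % 8 == 0:
            version = 2
    rec = 6 if version == 1 else 8
    if len(body) % rec:
        raise AERParseError(
            f"{path}: truncated record at byte {offset + (len(body) // rec) * rec}"
        )
    if version == 1:
        arr = np.frombuffer(body, dtype=np.dtype([("addr", ">u2"), ("ts", ">u4")]))
    else:
        arr = np.frombuffer(body, dtype=np.dtype([("addr", ">u4"), ("ts", ">u4")]))
    x, y, pol = _unpack_addresses(arr["addr"].astype(np.uint32))
    ts = arr["ts"].astype(np.int64)
    return EventStream(ts, x, y, pol, width=width, height=height)


def _write_jaer(stream: EventStream, path: Path, version: int = 2) -> None:
    with open(path, "wb") as fh:
        if version == 2:
            fh.write(_V2_MAGIC + b"\r\n")
            fh.write(b"# DVS128 address-event recording\r\n")
            fh.write(f"# dimensions {stream.width} {stream.height}\r\n".encode())
        addr = _pack_addresses(stream)
        ts = stream.timestamp_us.astype(np.uint32)
        if version == 2:
            out = np.empty(len(stream), dtype=np.dtype([("addr", ">u4"), ("ts", ">u4")]))
            out["addr"] = addr
        else:
            out = np.empty(len(stream), dtype=np.dtype([("addr", ">u2"), ("ts", ">u4")]))
            out["addr"] = addr.astype(np.uint16)
        out["ts"] = ts
        fh.write(out.tobytes())


_CSV_COLUMNS = ["timestamp_us", "x", "y", "polarity"]


def _read_csv(path: Path, width: int, height: int) -> EventStream:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message varies
        raise AERParseError(f"{path}: {exc}") from exc
    if list(df.columns) != _CSV_COLUMNS:
        raise AERParseError(
            f"{path}: line 1: expected header {','.join(_CSV_COLUMNS)!r}, "
            f"got {','.join(map(str, df.columns))!r}"
        )
    for col in _CSV_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            # +2: 1-based line numbers plus the header line.
            raise AERParseError(
                f"{path}: line {int(bad.idxmax()) + 2}: non-numeric {col!r} field"
            )
        df[col] = vals
    return EventStream(
        df["timestamp_us"].to_numpy(np.int64),
        df["x"].to_numpy(np.int64),
        df["y"].to_numpy(np.int64),
        df["polarity"].to_numpy(np.int64),
        width=width,
        height=height,
    )


def read_events(
    path, dialect: str = "jaer", width: int = 128, height: int = 128
) -> EventStream:
    """Read an event stream from ``path``.

    Out-of-order timestamps are sorted with a logged warning; events
    outside the sensor bounds raise :class:`ValidationError`.
    """
    path = Path(path)
    if dialect == "jaer":
        stream = _read_jaer(path, width, height)
    elif dialect == "csv":
        stream = _read_csv(path, width, height)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if len(stream) and np.any(np.diff(stream.timestamp_us) < 0):
        logger.warning("%s: out-of-order timestamps; sorting", path)
        stream = stream.sorted()
    return stream.validate()


def write_events(stream: EventStream, path, dialect: str = "jaer"):
    """Write ``stream`` so that :func:`read_events` recovers it exactly."""
    stream.validate()
    path = Path(path)
    if dialect == "jaer":
        _write_jaer(stream, path)
    elif dialect == "csv":
        pd.DataFrame(
            {
                "timestamp_us": stream.timestamp_us,
                "x": stream.x,
                "y": stream.y,
                "polarity": stream.polarity,
            }
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def filter_periodic_artifact(
    stream: EventStream, frequency_hz: float, n_bins: int = 20, factor: float = 3.0
) -> EventStream:
    """Remove events phase-locked to a periodic timestamp artifact.

    Timestamps are folded modulo the artifact period into an
    ``n_bins``-bin phase histogram.  If the fullest bin holds more than
    ``factor`` times the mean bin count, the events in that single bin
    are dropped; otherwise the stream is returned unchanged.
    """
    if frequency_hz <= 0:
        raise ValueError("frequency_hz must be positive")
    if len(stream) == 0:
        return stream
    period = 1e6 / frequency_hz
    phase_bin = ((stream.timestamp_us % period) / period * n_bins).astype(np.int64)
    phase_bin = np.clip(phase_bin, 0, n_bins - 1)
    counts = np.bincount(phase_bin, minlength=n_bins)
    dominant = int(np.argmax(counts))
    if counts[dominant] <= factor * counts.mean():
        return stream
    keep = phase_bin != dominant
    logger.info(
        "periodic artifact at %.3g Hz: dropping %d phase-locked events",
        frequency_hz,
        int((~keep).sum()),
    )
    return EventStream(
        stream.timestamp_us[keep],
        stream.x[keep],
        stream.y[keep],
        stream.polarity[keep],
        width=stream.width,
        height=stream.height,
        duration_us=stream.duration_us,
    )
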