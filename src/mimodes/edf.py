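"""Minimal European Data Format (EDF) reader and writer.

Covers plain continuous EDF with a single data record per file (enough for
trial-per-file storage): ASCII fixed-width headers, 16-bit little-endian
samples, physical scaling from the per-signal calibration fields.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import DegenerateInputError


def _field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, data: np.ndarray, channel_names: list[str], sampling_rate: float) -> None:
    """Write (channels x samples) data as one EDF data record."""
    x = np.asarray(data, dtype=np.float64)
    ns, n = x.shape
    if len(channel_names) != ns:
        raise DegenerateInputError("channel_names length must match rows")
    duration = n / sampling_rate
    pmin = x.min(axis=1)
    pmax = x.max(axis=1)
    span = pmax - pmin
    pmax = np.where(span == 0, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767

    hdr = b""
    hdr += _field("0", 8)  # version
    hdr += _field("mimodes", 80)  # patient id
    hdr += _field("synthetic", 80)  # recording id
    hdr += _field("01.01.00", 8)
    hdr += _field("00.00.00", 8)
    hdr += _field(256 + ns * 256, 8)
    hdr += _field("", 44)
    hdr += _field(1, 8)  # number of data records
    hdr += _field(f"{duration:g}", 8)
    hdr += _field(ns, 4)
    for nm in channel_names:
        hdr += _field(nm, 16)
    hdr += b"".join(_field("", 80) for _ in range(ns))  # transducer
    hdr += b"".join(_field("uV", 8) for _ in range(ns))
    hdr += b"".join(_field(f"{v:.8g}"[:8], 8) for v in pmin)
    hdr += b"".join(_field(f"{v:.8g}"[:8], 8) for v in pmax)
    hdr += b"".join(_field(dmin, 8) for _ in range(ns))
    hdr += b"".join(_field(dmax, 8) for _ in range(ns))
    hdr += b"".join(_field("", 80) for _ in range(ns))  # prefiltering
    hdr += b"".join(_field(n, 8) for _ in range(ns))
    hdr += b"".join(_field("", 32) for _ in range(ns))

    payload = b""
    for c in range(ns):
        gain = (pmax[c] - pmin[c]) / (dmax - dmin)
        dig = np.round((x[c] - pmin[c]) / gain + dmin).astype("<i2")
        payload += dig.tobytes()
    Path(path).write_bytes(hdr + payload)


def read_edf(path) -> tuple[np.ndarray, list[str], float]:
    """Read an EDF file -> (channels x samples, channel names, sampling rate).

    Multiple data records are concatenated; all signals must share a sample
    count per record.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise DegenerateInputError(f"{path}: truncated EDF header")

    def ascii_at(start, width):
        return raw[start : start + width].decode("ascii", "replace").strip()

    n_records = int(ascii_at(236, 8))
    duration = float(ascii_at(244, 8))
    ns = int(ascii_at(252, 4))
    base = 256
    names = [ascii_at(base + 16 * i, 16) for i in range(ns)]
    off = base + ns * (16 + 80 + 8)
    pmin = np.array([float(ascii_at(off + 8 * i, 8)) for i in range(ns)])
    off += ns * 8
    pmax = np.array([float(ascii_at(off + 8 * i, 8)) for i in range(ns)])
    off += ns * 8
    dmin = np.array([float(ascii_at(off + 8 * i, 8)) for i in range(ns)])
    off += ns * 8
    dmax = np.array([float(ascii_at(off + 8 * i, 8)) for i in range(ns)])
    off += ns * 8 + ns * 80
    nsamp = [int(ascii_at(off + 8 * i, 8)) for i in range(ns)]
    if len(set(nsamp)) != 1:
        raise DegenerateInputError(f"{path}: per-signal sample counts differ")
    n = nsamp[0]
    header_bytes = 256 + ns * 256
    if n_records < 0:  # unknown record count: infer from file size
        n_records = (len(raw) - header_bytes) // (2 * n * ns)
    data = np.empty((ns, n * n_records))
    pos = header_bytes
    for r in range(n_records):
        for c in range(ns):
            dig = np.frombuffer(raw, dtype="<i2", count=n, offset=pos)
            gain = (pmax[c] - pmin[c]) / (dmax[c] - dmin[c])
            data[c, r * n : (r + 1) * n] = (dig - dmin[c]) * gain + pmin[c]
            pos += 2 * n
    fs = n / duration if duration > 0 else float(n)
    return data, names, fs
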