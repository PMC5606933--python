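"""Minimal EDF (European Data Format) reader/writer.

Supports the subset needed for session storage: one fixed sample rate per
signal, 16-bit samples, 1-second data records. Header fields follow the
EDF specification (256-byte fixed header + 256 bytes per signal).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_HDR = 256
_DIG_MIN = -32768
_DIG_MAX = 32767


@dataclass
class EdfSignalHeader:
    label: str
    physical_min: float
    physical_max: float
    samples_per_record: int
    transducer: str = ""
    dimension: str = "uV"
    digital_min: int = _DIG_MIN
    digital_max: int = _DIG_MAX
    prefiltering: str = ""


@dataclass
class EdfFile:
    """In-memory EDF contents: per-signal float arrays in physical units."""

    signals: list[np.ndarray]
    headers: list[EdfSignalHeader]
    record_duration: float = 1.0
    start: _dt.datetime = field(
        default_factory=lambda: _dt.datetime(2000, 1, 1, 0, 0, 0)
    )

    @property
    def labels(self) -> list[str]:
        return [h.label for h in self.headers]


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw.ljust(width)


def _fmt_float(value: float, width: int) -> bytes:
    for prec in range(width, -1, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= width:
            return _pad(s, width)
    return _pad("0", width)


def write_edf(path: str | Path, edf: EdfFile) -> None:
    """Write signals to ``path``. Signals are zero-padded to a whole number
    of records; true sample counts are not stored (EDF has no field for
    them), so callers needing exact lengths must track them externally."""
    path = Path(path)
    ns = len(edf.signals)
    if ns == 0:
        raise ValueError("no signals to write")
    if len(edf.headers) != ns:
        raise ValueError("signal/header count mismatch")

    n_records = 0
    for sig, hdr in zip(edf.signals, edf.headers):
        n_records = max(
            n_records, int(np.ceil(len(sig) / hdr.samples_per_record))
        )

    digital = []
    for sig, hdr in zip(edf.signals, edf.headers):
        total = n_records * hdr.samples_per_record
        padded = np.zeros(total, dtype=float)
        padded[: len(sig)] = sig
        prange = hdr.physical_max - hdr.physical_min
        if prange <= 0:
            raise ValueError(f"invalid physical range for {hdr.label!r}")
        scale = prange / (hdr.digital_max - hdr.digital_min)
        dig = np.round((padded - hdr.physical_min) / scale) + hdr.digital_min
        dig = np.clip(dig, hdr.digital_min, hdr.digital_max)
        digital.append(dig.astype("<i2"))

    header_bytes = _HDR * (1 + ns)
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad("Startdate X X X X", 80))
        fh.write(_pad(edf.start.strftime("%d.%m.%y"), 8))
        fh.write(_pad(edf.start.strftime("%H.%M.%S"), 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_fmt_float(edf.record_duration, 8))
        fh.write(_pad(str(ns), 4))

        for hdr in edf.headers:
            fh.write(_pad(hdr.label, 16))
        for hdr in edf.headers:
            fh.write(_pad(hdr.transducer, 80))
        for hdr in edf.headers:
            fh.write(_pad(hdr.dimension, 8))
        for hdr in edf.headers:
            fh.write(_fmt_float(hdr.physical_min, 8))
        for hdr in edf.headers:
            fh.write(_fmt_float(hdr.physical_max, 8))
        for hdr in edf.headers:
            fh.write(_pad(str(hdr.digital_min), 8))
        for hdr in edf.headers:
            fh.write(_pad(str(hdr.digital_max), 8))
        for hdr in edf.headers:
            fh.write(_pad(hdr.prefiltering, 80))
        for hdr in edf.headers:
            fh.write(_pad(str(hdr.samples_per_record), 8))
        for _ in edf.headers:
            fh.write(_pad("", 32))

        for rec in range(n_records):
            for sig_idx in range(ns):
                spr = edf.headers[sig_idx].samples_per_record
                chunk = digital[sig_idx][rec * spr : (rec + 1) * spr]
                fh.write(chunk.tobytes())


def read_edf(path: str | Path) -> EdfFile:
    path = Path(path)
    with open(path, "rb") as fh:
        raw = fh.read()

    def ascii_at(offset: int, width: int) -> str:
        return raw[offset : offset + width].decode("ascii").strip()

    date_s = ascii_at(168, 8)
    time_s = ascii_at(176, 8)
    n_records = int(ascii_at(236, 8))
    record_duration = float(ascii_at(244, 8))
    ns = int(ascii_at(252, 4))

    base = _HDR

    def sig_field(block: int, width: int, idx: int) -> str:
        offset = base + block + idx * width
        return raw[offset : offset + width].decode("ascii").strip()

    headers = []
    blocks = [16, 80, 8, 8, 8, 8, 8, 80, 8]
    offsets = np.concatenate([[0], np.cumsum([b * ns for b in blocks])])
    for i in range(ns):
        headers.append(
            EdfSignalHeader(
                label=sig_field(int(offsets[0]), 16, i),
                transducer=sig_field(int(offsets[1]), 80, i),
                dimension=sig_field(int(offsets[2]), 8, i),
                physical_min=float(sig_field(int(offsets[3]), 8, i)),
                physical_max=float(sig_field(int(offsets[4]), 8, i)),
                digital_min=int(sig_field(int(offsets[5]), 8, i)),
                digital_max=int(sig_field(int(offsets[6]), 8, i)),
                prefiltering=sig_field(int(offsets[7]), 80, i),
                samples_per_record=int(sig_field(int(offsets[8]), 8, i)),
            )
        )

    data_start = base + int(offsets[-1]) + 32 * ns
    record_len = sum(h.samples_per_record for h in headers)
    data = np.frombuffer(
        raw, dtype="<i2", count=n_records * record_len, offset=data_start
    ).reshape(n_records, record_len)

    signals = []
    col = 0
    for hdr in headers:
        spr = hdr.samples_per_record
        dig = data[:, col : col + spr].reshape(-1).astype(float)
        col += spr
        scale = (hdr.physical_max - hdr.physical_min) / (
            hdr.digital_max - hdr.digital_min
        )
        signals.append((dig - hdr.digital_min) * scale + hdr.physical_min)

    try:
        start = _dt.datetime.strptime(date_s + " " + time_s, "%d.%m.%y %H.%M.%S")
    except ValueError:
        start = _dt.datetime(2000, 1, 1)

    return EdfFile(
        signals=signals,
        headers=headers,
        record_duration=record_duration,
        start=start,
    )
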