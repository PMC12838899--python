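"""Minimal EDF (European Data Format) reader/writer.

Supports plain EDF with referential signal labels and 16-bit samples —
enough for round-tripping multichannel scalp EEG. EDF+ annotations, BDF
and discontinuous files are out of scope.

All signals are written into a single data record whose duration equals
the full recording, which keeps the sample count exact for any length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

HEADER_SIZE = 256
SIGNAL_HEADER_SIZE = 256
DIG_MIN, DIG_MAX = -32768, 32767


@dataclass
class EdfSignal:
    label: str
    physical_dim: str
    data: np.ndarray  # float64, physical units


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long ({s!r} > {width} chars)")
    return s.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int = 8) -> str:
    """Shortest ASCII float representation fitting the fixed-width field."""
    for p in range(7, 0, -1):
        s = f"{x:.{p}g}"
        if len(s) <= width:
            return s
    return f"{x:.0f}"[:width]


def write_edf(path, signals: list[EdfSignal], fs: float, patient_id: str = "X",
              start: str = "01.01.00", time: str = "00.00.00") -> None:
    if not signals:
        raise ValueError("cannot write an EDF file with zero signals")
    n = signals[0].data.size
    if any(s.data.size != n for s in signals):
        raise ValueError("all EDF signals must share one sample count")
    ns = len(signals)
    record_dur = n / fs

    phys_lo, phys_hi, scaled = [], [], []
    for s in signals:
        x = np.asarray(s.data, dtype=np.float64)
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            hi = lo + 1.0
        # round outward so the 8-char ASCII fields still bracket the data
        lo_s, hi_s = _fmt_float(math.floor(lo)), _fmt_float(math.ceil(hi))
        lo_w, hi_w = float(lo_s), float(hi_s)
        gain = (DIG_MAX - DIG_MIN) / (hi_w - lo_w)
        dig = np.round((x - lo_w) * gain + DIG_MIN).astype(np.int16)
        phys_lo.append(lo_s)
        phys_hi.append(hi_s)
        scaled.append(dig)

    header_bytes = HEADER_SIZE + ns * SIGNAL_HEADER_SIZE
    with open(path, "wb") as f:
        f.write(_field("0", 8))
        f.write(_field(patient_id, 80))
        f.write(_field("", 80))
        f.write(_field(start, 8))
        f.write(_field(time, 8))
        f.write(_field(str(header_bytes), 8))
        f.write(_field("", 44))
        f.write(_field("1", 8))  # one data record
        f.write(_field(_fmt_float(record_dur), 8))
        f.write(_field(str(ns), 4))

        for s in signals:
            f.write(_field(s.label, 16))
        for _ in signals:
            f.write(_field("", 80))  # transducer
        for s in signals:
            f.write(_field(s.physical_dim, 8))
        for lo_s in phys_lo:
            f.write(_field(lo_s, 8))
        for hi_s in phys_hi:
            f.write(_field(hi_s, 8))
        f.write(_field(str(DIG_MIN), 8) * ns)
        f.write(_field(str(DIG_MAX), 8) * ns)
        for _ in signals:
            f.write(_field("", 80))  # prefiltering
        f.write(_field(str(n), 8) * ns)
        f.write(_field("", 32) * ns)

        for dig in scaled:
            f.write(dig.astype("<i2").tobytes())


def read_edf(path) -> tuple[list[EdfSignal], float, str]:
    """Returns (signals, fs, patient_id)."""
    with open(path, "rb") as f:
        head = f.read(HEADER_SIZE)
        if len(head) < HEADER_SIZE:
            raise ValueError("truncated EDF header")
        patient_id = head[8:88].decode("ascii", "replace").strip()
        n_records = int(head[236:244].decode("ascii").strip())
        record_dur = float(head[244:252].decode("ascii").strip())
        ns = int(head[252:256].decode("ascii").strip())
        if ns <= 0 or n_records < 0:
            raise ValueError("invalid EDF header counts")

        def block(width: int) -> list[str]:
            raw = f.read(width * ns)
            return [raw[i * width:(i + 1) * width].decode("ascii", "replace").strip()
                    for i in range(ns)]

        labels = block(16)
        block(80)  # transducer
        dims = block(8)
        p_lo = [float(v) for v in block(8)]
        p_hi = [float(v) for v in block(8)]
        d_lo = [int(v) for v in block(8)]
        d_hi = [int(v) for v in block(8)]
        block(80)  # prefiltering
        spr = [int(v) for v in block(8)]
        block(32)  # reserved

        chunks: list[list[np.ndarray]] = [[] for _ in range(ns)]
        for _ in range(n_records):
            for i in range(ns):
                raw = np.frombuffer(f.read(2 * spr[i]), dtype="<i2")
                if raw.size != spr[i]:
                    raise ValueError("truncated EDF data record")
                chunks[i].append(raw)

    signals = []
    fs = spr[0] * n_records / (record_dur * n_records) if n_records else 0.0
    for i in range(ns):
        dig = np.concatenate(chunks[i]) if chunks[i] else np.empty(0, dtype="<i2")
        gain = (p_hi[i] - p_lo[i]) / (d_hi[i] - d_lo[i])
        phys = (dig.astype(np.float64) - d_lo[i]) * gain + p_lo[i]
        signals.append(EdfSignal(label=labels[i], physical_dim=dims[i], data=phys))
    return signals, fs, patient_id
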