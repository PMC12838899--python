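"""Recording / annotation I/O and montage harmonization.

Formats:

* ``csv`` — text channel matrix; first column is time (or index), remaining
  columns are electrodes, header row carries the labels.
* ``edf`` — plain EDF via the bundled minimal codec.
* ``container`` — NumPy ``.npz`` archive (lossless float64), the internal
  round-trip format.

Annotations travel as a CSV with columns
``patient_id, seizure_id, onset_s, offset_s`` at 0.01 s precision.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import _edf
from .montage import validate_labels

FORMATS = ("edf", "csv", "container")

#: Annotation time grid (seconds).
TIME_GRID_S = 0.01


class MontageError(ValueError):
    """A requested electrode is absent from the recording."""


@dataclass
class Recording:
    """A multichannel EEG recording (microvolts)."""

    patient_id: str
    channel_labels: list[str]
    data: np.ndarray  # shape (n_channels, n_samples)
    fs: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be a channel x sample matrix")
        self.channel_labels = validate_labels(self.channel_labels)
        if len(self.channel_labels) == 0:
            raise ValueError("recording must have at least one channel")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows for "
                f"{len(self.channel_labels)} channel labels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _round_grid(t: float) -> float:
    """Round-half-up onto the 0.01 s annotation grid."""
    return float(np.floor(t / TIME_GRID_S + 0.5) * TIME_GRID_S)


@dataclass(frozen=True)
class SeizureAnnotation:
    """One seizure event, times in seconds from the recording origin."""

    patient_id: str
    seizure_id: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "onset_s", _round_grid(self.onset_s))
        object.__setattr__(self, "offset_s", _round_grid(self.offset_s))
        if self.offset_s <= self.onset_s:
            raise ValueError(
                f"seizure {self.seizure_id}: offset {self.offset_s} "
                f"<= onset {self.onset_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class LabelSequence:
    """Per-sample binary labels aligned with a recording."""

    labels: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be binary, found {sorted(bad)}")


# ---------------------------------------------------------------------------
# Recording I/O


def read_recording(path, format_id: str, patient_id: str | None = None) -> Recording:
    path = Path(path)
    if format_id not in FORMATS:
        raise ValueError(f"unknown format {format_id!r}; expected one of {FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)

    if format_id == "csv":
        return _read_csv(path, patient_id)
    if format_id == "edf":
        signals, fs, pid = _edf.read_edf(path)
        labels = [s.label for s in signals]
        data = np.vstack([s.data for s in signals])
        return Recording(patient_id or pid or path.stem, labels, data, fs)
    # container
    with np.load(path, allow_pickle=False) as z:
        labels = [str(l) for l in z["channel_labels"]]
        return Recording(
            patient_id or str(z["patient_id"]),
            labels,
            z["data"],
            float(z["fs"]),
            float(z["start_time_s"]),
        )


def _read_csv(path: Path, patient_id: str | None) -> Recording:
    try:
        df = pd.read_csv(path)
    except ValueError as e:
        raise ValueError(f"cannot parse CSV recording {path}: {e}") from e
    if df.shape[1] < 2:
        raise ValueError("CSV recording needs a time column plus >=1 channel")
    # pandas mangles duplicate column names, so check the raw header line
    with open(path) as fh:
        raw_header = [c.strip() for c in fh.readline().rstrip("\n").split(",")]
    raw_channels = [c.upper() for c in raw_header[1:]]
    if len(set(raw_channels)) != len(raw_channels):
        raise ValueError("duplicate channel names in CSV header")
    labels = [str(c) for c in df.columns[1:]]
    vals = df.iloc[:, 1:].to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValueError(f"non-numeric samples in CSV recording {path}")
    tcol = df.iloc[:, 0].to_numpy(dtype=np.float64)
    if tcol.size >= 2:
        dt = np.diff(tcol)
        fs = 1.0 / np.median(dt) if np.all(dt > 0) else 256.0
        if np.allclose(np.diff(tcol), 1.0):  # plain index column
            fs = 256.0
    else:
        fs = 256.0
    return Recording(patient_id or path.stem, labels, vals.T, float(round(fs, 6)))


def write_recording(rec: Recording, path, format_id: str) -> Path:
    path = Path(path)
    if format_id not in FORMATS:
        raise ValueError(f"unknown format {format_id!r}; expected one of {FORMATS}")
    if format_id == "csv":
        t = np.arange(rec.n_samples) / rec.fs + rec.start_time_s
        df = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
        df.insert(0, "t", t)
        df.to_csv(path, index=False, float_format="%.10g")
    elif format_id == "edf":
        signals = [
            _edf.EdfSignal(label=lab, physical_dim="uV", data=rec.data[i])
            for i, lab in enumerate(rec.channel_labels)
        ]
        _edf.write_edf(path, signals, rec.fs, patient_id=rec.patient_id)
    else:
        np.savez_compressed(
            path,
            patient_id=np.str_(rec.patient_id),
            channel_labels=np.array(rec.channel_labels),
            data=rec.data,
            fs=np.float64(rec.fs),
            start_time_s=np.float64(rec.start_time_s),
        )
    return path


# ---------------------------------------------------------------------------
# Annotations


def read_annotations(path) -> list[SeizureAnnotation]:
    df = pd.read_csv(path)
    required = {"patient_id", "seizure_id", "onset_s", "offset_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    anns = [
        SeizureAnnotation(
            patient_id=str(r.patient_id),
            seizure_id=str(r.seizure_id),
            onset_s=float(r.onset_s),
            offset_s=float(r.offset_s),
        )
        for r in df.itertuples()
    ]
    anns.sort(key=lambda a: (a.patient_id, a.onset_s))
    _check_disjoint(anns)
    return anns


def write_annotations(anns, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "patient_id": [a.patient_id for a in anns],
            "seizure_id": [a.seizure_id for a in anns],
            "onset_s": [f"{a.onset_s:.2f}" for a in anns],
            "offset_s": [f"{a.offset_s:.2f}" for a in anns],
        }
    )
    df.to_csv(path, index=False)
    return path


def _check_disjoint(anns) -> None:
    by_patient: dict[str, list[SeizureAnnotation]] = {}
    for a in anns:
        by_patient.setdefault(a.patient_id, []).append(a)
    for pid, events in by_patient.items():
        events = sorted(events, key=lambda a: a.onset_s)
        for prev, cur in zip(events, events[1:]):
            if cur.onset_s < prev.offset_s:
                raise ValueError(
                    f"patient {pid}: seizures {prev.seizure_id} and "
                    f"{cur.seizure_id} overlap"
                )


def annotations_to_labels(
    anns, fs: float, n_samples: int
) -> LabelSequence:
    """Per-sample labels: sample i is 1 iff i/fs in [onset, offset)."""
    span = n_samples / fs
    labels = np.zeros(n_samples, dtype=np.int8)
    for a in anns:
        if a.onset_s < 0 or a.offset_s > span + 1e-9:
            raise ValueError(
                f"seizure {a.seizure_id} [{a.onset_s}, {a.offset_s}) outside "
                f"recording span [0, {span:.2f})"
            )
        lo = int(np.ceil(a.onset_s * fs - 1e-9))
        hi = int(np.ceil(a.offset_s * fs - 1e-9))
        labels[lo:hi] = 1
    return LabelSequence(labels=labels, fs=fs)


# ---------------------------------------------------------------------------
# Montage


def harmonize_montage(rec: Recording, target_labels) -> Recording:
    """Reorder/subset channels to exactly ``target_labels`` (in order)."""
    target = validate_labels(target_labels)
    index = {lab: i for i, lab in enumerate(rec.channel_labels)}
    missing = [lab for lab in target if lab not in index]
    if missing:
        raise MontageError(
            f"recording {rec.patient_id} lacks electrodes: {missing}"
        )
    rows = [index[lab] for lab in target]
    return replace(
        rec, channel_labels=list(target), data=rec.data[rows].copy()
    )
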