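"""Frame and packet construction.

A recording is cut into non-overlapping 0.5 s windows (128 samples at
256 Hz). Each window contributes, per feature step:

* the raw value of every channel (C values),
* the arithmetic-mean channel (1 value),
* a single-level db4 wavelet decomposition of the window's mean channel
  (67 approximation + 67 detail = 134 values, constant across the window).

Total feature dimension is therefore C + 135 (141 for 6 electrodes, 154
for the 19-channel montage).

Class balancing pairs every seizure segment with an equal-duration
interictal segment from the same recording; balanced segments are then
concatenated into 300 s packets of 600 frames.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._dwt import dwt_output_len, dwt_single
from .eeg_io import LabelSequence, Recording, SeizureAnnotation, annotations_to_labels


class BalancingError(ValueError):
    """Not enough interictal signal to pair with a seizure segment."""


@dataclass
class FrameConfig:
    window_s: float = 0.5
    fs: float = 256.0
    wavelet_name: str = "db4"
    wavelet_level: int = 1
    extension_mode: str = "symmetric"
    label_rule: float = 0.5
    packet_s: float = 300.0
    balance_buffer_s: float = 30.0

    def __post_init__(self) -> None:
        w = self.window_s * self.fs
        if abs(w - round(w)) > 1e-9 or round(w) < 2:
            raise ValueError("window_s * fs must be an integer >= 2")
        if self.wavelet_level < 1:
            raise ValueError("wavelet_level must be >= 1")
        if self.extension_mode != "symmetric":
            raise ValueError("only symmetric boundary extension is supported")
        if not (0.0 < self.label_rule <= 1.0):
            raise ValueError("label_rule must be in (0, 1]")

    @property
    def window_len(self) -> int:
        return int(round(self.window_s * self.fs))

    @property
    def frames_per_packet(self) -> int:
        return int(round(self.packet_s / self.window_s))

    @property
    def n_wavelet_features(self) -> int:
        n, total = self.window_len, 0
        for _ in range(self.wavelet_level):
            n = dwt_output_len(n, self.wavelet_name)
            total += n
        return total + n  # final approximation + all detail bands


@dataclass
class Window:
    index: int
    t_start_s: float
    data: np.ndarray  # (C, window_len)
    sample_labels: np.ndarray  # (window_len,)


@dataclass(eq=False)
class FeatureFrame:
    window_index: int
    t_start_s: float
    raw_features: np.ndarray  # per-channel window mean, (C,)
    mean_feature: float
    wavelet_features: np.ndarray  # (134,) under defaults
    label: int
    seizure_id: str | None = None


@dataclass
class SampleSequence:
    """Per-sample feature rows for a run of windows (one packet/segment)."""

    features: np.ndarray  # (n_windows * window_len, C + 1 + n_wavelet)
    labels: np.ndarray  # (n_windows * window_len,)
    window_len: int


@dataclass
class Segment:
    kind: str  # "ictal" | "interictal"
    start_s: float
    end_s: float
    seizure_id: str | None
    segment_id: str

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class FramedSegment:
    segment: Segment
    frames: list[FeatureFrame]
    samples: SampleSequence


@dataclass(eq=False)
class Packet:
    """Up to 300 s of contiguous-in-segment feature frames."""

    frame_features: np.ndarray  # (F, D)
    frame_labels: np.ndarray  # (F,)
    frame_times: np.ndarray  # (F,) window start seconds
    seizure_ids: list[str | None]
    samples: np.ndarray  # (F * window_len, D)
    sample_labels: np.ndarray  # (F * window_len,)
    window_len: int
    partial: bool = False
    provenance: list[str] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.frame_features.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.frame_features.shape[1]


# ---------------------------------------------------------------------------
# Core operations


def window_signal(
    rec: Recording, labels: LabelSequence, cfg: FrameConfig,
    t_offset_s: float = 0.0,
) -> list[Window]:
    """Cut into non-overlapping windows; trailing partial window dropped."""
    if abs(rec.fs - cfg.fs) > 1e-9:
        raise ValueError(f"recording fs {rec.fs} != configured fs {cfg.fs}")
    if labels.labels.size != rec.n_samples:
        raise ValueError("label sequence length does not match recording")
    W = cfg.window_len
    n_win = rec.n_samples // W
    return [
        Window(
            index=k,
            t_start_s=t_offset_s + k * cfg.window_s,
            data=rec.data[:, k * W:(k + 1) * W],
            sample_labels=labels.labels[k * W:(k + 1) * W],
        )
        for k in range(n_win)
    ]


def mean_channel(window: np.ndarray) -> np.ndarray:
    """Unweighted per-sample mean across channels."""
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 2 or window.shape[0] < 1:
        raise ValueError("expected a channel x sample matrix")
    return window.mean(axis=0)


def wavelet_features(x: np.ndarray, cfg: FrameConfig) -> np.ndarray:
    """Wavelet coefficient vector of one window's mean channel.

    Level 1 (the default): approximation then detail coefficients,
    2 * floor((n + L - 1) / 2) values — 134 for n=128, db4.
    Higher levels recurse on the approximation band; output is
    [approx_L, detail_L, ..., detail_1].
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size != cfg.window_len:
        raise ValueError(
            f"expected a {cfg.window_len}-sample vector, got shape {x.shape}"
        )
    approx = x
    details: list[np.ndarray] = []
    for _ in range(cfg.wavelet_level):
        approx, det = dwt_single(approx, cfg.wavelet_name)
        details.append(det)
    return np.concatenate([approx] + details[::-1])


def assemble_frames(
    windows: list[Window], cfg: FrameConfig, seizure_id: str | None = None
) -> tuple[list[FeatureFrame], SampleSequence]:
    """Feature frames + per-sample sequence for a run of windows."""
    W = cfg.window_len
    n_wav = cfg.n_wavelet_features
    if not windows:
        dim = 1 + n_wav
        empty = np.empty((0, dim))
        return [], SampleSequence(empty, np.empty(0, dtype=np.int8), W)

    C = windows[0].data.shape[0]
    dim = C + 1 + n_wav
    frames: list[FeatureFrame] = []
    rows = np.empty((len(windows) * W, dim))
    row_labels = np.empty(len(windows) * W, dtype=np.int8)
    for j, win in enumerate(windows):
        mc = mean_channel(win.data)
        wav = wavelet_features(mc, cfg)
        frac = float(win.sample_labels.mean()) if W else 0.0
        label = int(frac >= cfg.label_rule)
        frames.append(
            FeatureFrame(
                window_index=win.index,
                t_start_s=win.t_start_s,
                raw_features=win.data.mean(axis=1),
                mean_feature=float(mc.mean()),
                wavelet_features=wav,
                label=label,
                seizure_id=seizure_id,
            )
        )
        block = rows[j * W:(j + 1) * W]
        block[:, :C] = win.data.T
        block[:, C] = mc
        block[:, C + 1:] = wav[None, :]
        row_labels[j * W:(j + 1) * W] = win.sample_labels
    return frames, SampleSequence(rows, row_labels, W)


# ---------------------------------------------------------------------------
# Balancing


def _free_intervals(
    duration_s: float, ann: list[SeizureAnnotation], buffer_s: float,
    taken: list[tuple[float, float]],
) -> list[tuple[float, float]]:
    blocked = sorted(
        [(max(0.0, a.onset_s - buffer_s), min(duration_s, a.offset_s + buffer_s))
         for a in ann] + [(s, e) for s, e in taken]
    )
    free, cursor = [], 0.0
    for lo, hi in blocked:
        if lo > cursor:
            free.append((cursor, lo))
        cursor = max(cursor, hi)
    if cursor < duration_s:
        free.append((cursor, duration_s))
    return free


def balance_segments(
    rec: Recording,
    ann: list[SeizureAnnotation],
    labels: LabelSequence,
    cfg: FrameConfig,
    seed: int = 0,
) -> list[Segment]:
    """One equal-duration interictal segment per seizure segment.

    Deterministic: the interictal segment is the earliest feasible start at
    or after a seeded offset into the recording (wrapping to the earliest
    feasible start overall). Chosen segments never overlap each other, any
    seizure, or the +-buffer exclusion zone around seizures.
    """
    rng = np.random.default_rng(seed)
    duration = rec.duration_s
    taken: list[tuple[float, float]] = []
    out: list[Segment] = []
    for a in sorted(ann, key=lambda a: a.onset_s):
        out.append(
            Segment("ictal", a.onset_s, a.offset_s, a.seizure_id,
                    segment_id=f"{a.seizure_id}:ictal")
        )
        need = a.duration_s
        t0 = float(rng.uniform(0.0, duration))
        free = _free_intervals(duration, ann, cfg.balance_buffer_s, taken)
        starts = [max(lo, t0) for lo, hi in free if hi - max(lo, t0) >= need]
        if not starts:
            starts = [lo for lo, hi in free if hi - lo >= need]
        if not starts:
            raise BalancingError(
                f"no {need:.2f} s interictal stretch available to balance "
                f"seizure {a.seizure_id}"
            )
        start = min(starts)
        # snap to the sample grid so windowing is exact
        start = round(start * rec.fs) / rec.fs
        taken.append((start, start + need))
        out.append(
            Segment("interictal", start, start + need, a.seizure_id,
                    segment_id=f"{a.seizure_id}:interictal")
        )
    return out


def frame_segments(
    rec: Recording,
    labels: LabelSequence,
    segments: list[Segment],
    cfg: FrameConfig,
) -> list[FramedSegment]:
    out = []
    for seg in segments:
        lo = int(round(seg.start_s * rec.fs))
        hi = int(round(seg.end_s * rec.fs))
        sub = Recording(
            rec.patient_id, rec.channel_labels, rec.data[:, lo:hi], rec.fs,
            start_time_s=seg.start_s,
        )
        sub_labels = LabelSequence(labels.labels[lo:hi], labels.fs)
        wins = window_signal(sub, sub_labels, cfg, t_offset_s=seg.start_s)
        sid = seg.seizure_id if seg.kind == "ictal" else None
        frames, samples = assemble_frames(wins, cfg, seizure_id=sid)
        out.append(FramedSegment(seg, frames, samples))
    return out


# ---------------------------------------------------------------------------
# Packetization


def packetize(framed: list[FramedSegment], cfg: FrameConfig) -> list[Packet]:
    """Concatenate framed segments into 300 s packets of 600 frames.

    The final partial packet is retained and flagged.
    """
    W = cfg.window_len
    per = cfg.frames_per_packet

    all_frames: list[FeatureFrame] = []
    sample_rows: list[np.ndarray] = []
    sample_labs: list[np.ndarray] = []
    frame_prov: list[str] = []
    for fs_ in framed:
        all_frames.extend(fs_.frames)
        F = len(fs_.frames)
        for j in range(F):
            sample_rows.append(fs_.samples.features[j * W:(j + 1) * W])
            sample_labs.append(fs_.samples.labels[j * W:(j + 1) * W])
            frame_prov.append(fs_.segment.segment_id)

    packets: list[Packet] = []
    for start in range(0, len(all_frames), per):
        chunk = all_frames[start:start + per]
        feats = np.stack(
            [np.concatenate([f.raw_features, [f.mean_feature], f.wavelet_features])
             for f in chunk]
        )
        packets.append(
            Packet(
                frame_features=feats,
                frame_labels=np.array([f.label for f in chunk], dtype=np.int8),
                frame_times=np.array([f.t_start_s for f in chunk]),
                seizure_ids=[f.seizure_id for f in chunk],
                samples=np.concatenate(sample_rows[start:start + per]),
                sample_labels=np.concatenate(sample_labs[start:start + per]),
                window_len=W,
                partial=len(chunk) < per,
                provenance=sorted(set(frame_prov[start:start + per])),
            )
        )
    return packets


def featurize_recording(
    rec: Recording,
    ann: list[SeizureAnnotation],
    cfg: FrameConfig,
    balance: bool = True,
    seed: int = 0,
    shuffle: bool = True,
) -> list[Packet]:
    """Full preprocessing chain: labels -> (balance) -> frames -> packets.

    Balanced segments are packed in seeded-shuffled order: the fixed
    ictal-then-interictal alternation would otherwise be a positional
    label cue for sequence models.
    """
    labels = annotations_to_labels(ann, rec.fs, rec.n_samples)
    if balance:
        segments = balance_segments(rec, ann, labels, cfg, seed=seed)
        if shuffle:
            rng = np.random.default_rng(seed + 424_243)
            segments = [segments[i] for i in rng.permutation(len(segments))]
    else:
        segments = [Segment("full", 0.0, rec.duration_s, None, f"{rec.patient_id}:full")]
        # tag ictal frames with their seizure id even in unbalanced mode
    framed = frame_segments(rec, labels, segments, cfg)
    if not balance and ann:
        for fs_ in framed:
            for f in fs_.frames:
                for a in ann:
                    if a.onset_s - 1e-9 <= f.t_start_s < a.offset_s:
                        f.seizure_id = a.seizure_id
    return packetize(framed, cfg)


# ---------------------------------------------------------------------------
# Container I/O (arrays in an .npz, FrameConfig in a JSON sidecar)


def save_packets(packets: list[Packet], cfg: FrameConfig, path) -> Path:
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    meta: dict = {"config": asdict(cfg), "packets": []}
    for i, p in enumerate(packets):
        arrays[f"p{i}_frame_features"] = p.frame_features
        arrays[f"p{i}_frame_labels"] = p.frame_labels
        arrays[f"p{i}_frame_times"] = p.frame_times
        arrays[f"p{i}_samples"] = p.samples
        arrays[f"p{i}_sample_labels"] = p.sample_labels
        meta["packets"].append(
            {
                "seizure_ids": [s or "" for s in p.seizure_ids],
                "window_len": p.window_len,
                "partial": p.partial,
                "provenance": p.provenance,
            }
        )
    np.savez_compressed(path, **arrays)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
    return path


def load_packets(path) -> tuple[list[Packet], FrameConfig]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    cfg = FrameConfig(**meta["config"])
    packets = []
    with np.load(path) as z:
        for i, pm in enumerate(meta["packets"]):
            packets.append(
                Packet(
                    frame_features=z[f"p{i}_frame_features"].copy(),
                    frame_labels=z[f"p{i}_frame_labels"].copy(),
                    frame_times=z[f"p{i}_frame_times"].copy(),
                    seizure_ids=[s or None for s in pm["seizure_ids"]],
                    samples=z[f"p{i}_samples"].copy(),
                    sample_labels=z[f"p{i}_sample_labels"].copy(),
                    window_len=pm["window_len"],
                    partial=pm["partial"],
                    provenance=list(pm["provenance"]),
                )
            )
    return packets, cfg
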