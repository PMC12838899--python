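"""Event-level evaluation and the composite performance score.

The composite score combines window accuracy, mean detection delay
(normalized by 13 s) and window recall on a 0-10 scale:

    score = 10 * [alpha * Acc + beta * max(0, 1 - DD/13) + gamma * Recall]

Weights are applied in that term order for every scheme W1-W6 (this is
the mapping that reproduces the published score columns from their own
accuracy/delay/recall values). Detections later than 7.41 s after onset
are flagged as suboptimal. Undetected seizures — events containing no
positive-predicted window — are counted separately and excluded from the
mean delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eeg_io import SeizureAnnotation

#: Delay above which a detection is flagged suboptimal (seconds).
MAX_ACCEPTABLE_DELAY_S = 7.41

#: Delay normalization constant (seconds): maximum observed delay.
DELAY_NORM_S = 13.0


@dataclass(frozen=True)
class ScoreWeights:
    alpha: float  # accuracy term
    beta: float  # delay term
    gamma: float  # recall term
    dd_norm_s: float = DELAY_NORM_S
    scale: float = 10.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("weights must be nonnegative")
        if abs(self.alpha + self.beta + self.gamma - 1.0) > 1e-9:
            raise ValueError("alpha + beta + gamma must equal 1")
        if self.dd_norm_s <= 0:
            raise ValueError("dd_norm_s must be positive")


def weighting_schemes() -> dict[str, ScoreWeights]:
    """The six published weighting triples, in (acc, delay, recall) order."""
    triples = {
        "W1": (0.4, 0.4, 0.2),
        "W2": (0.3, 0.5, 0.2),
        "W3": (0.25, 0.5, 0.25),
        "W4": (0.3, 0.4, 0.3),
        "W5": (0.2, 0.6, 0.2),
        "W6": (0.33, 0.33, 0.34),
    }
    return {name: ScoreWeights(*t) for name, t in triples.items()}


@dataclass
class EventDelay:
    seizure_id: str
    delay_s: float | None  # None when no qualifying run
    any_positive: bool  # any positive window inside [onset, offset)
    suboptimal: bool = False


@dataclass
class EventMetrics:
    accuracy: float
    recall: float
    precision: float
    mean_dd_s: float
    undetected: int
    n_seizures: int
    score: float | None = None
    dd_flags: list[str] = field(default_factory=list)
    per_event: list[EventDelay] = field(default_factory=list)


# ---------------------------------------------------------------------------


def window_confusion(pred, truth) -> tuple[float, float, float, int, int]:
    """(accuracy, recall, precision, FN, TS) over window labels."""
    pred = np.asarray(pred, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    ts = int((truth == 1).sum())
    if ts == 0:
        raise ValueError("no true seizure windows: recall undefined")
    fn = int(((truth == 1) & (pred == 0)).sum())
    tp = ts - fn
    fp = int(((truth == 0) & (pred == 1)).sum())
    accuracy = float((pred == truth).mean())
    recall = 1.0 - fn / ts
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    return accuracy, recall, float(precision), fn, ts


def _positive_runs(times: np.ndarray, preds: np.ndarray, window_s: float):
    """Maximal runs of consecutive positive windows.

    Consecutive means adjacent in index *and* contiguous in time (gaps in
    the time axis — e.g. segment boundaries inside a packet — break runs).
    Yields (start_time, end_time_exclusive, length).
    """
    runs = []
    start = None
    prev_t = None
    length = 0
    for t, p in zip(times, preds):
        contiguous = prev_t is not None and abs(t - prev_t - window_s) < 1e-6
        if p and (start is None or not contiguous):
            if start is not None:
                runs.append((start, prev_t + window_s, length))
            start, length = t, 1
        elif p:
            length += 1
        elif start is not None:
            runs.append((start, prev_t + window_s, length))
            start, length = None, 0
        prev_t = t
    if start is not None:
        runs.append((start, prev_t + window_s, length))
    return runs


def detection_delay(
    times,
    preds,
    event: SeizureAnnotation,
    run_len: int = 2,
    window_s: float = 0.5,
) -> EventDelay:
    """Delay from onset to the first qualifying positive run.

    A qualifying run has >= ``run_len`` consecutive positive windows and
    intersects [onset, offset). The delay is clamped at 0 for runs that
    start before onset. ``delay_s`` is None when no run qualifies;
    ``any_positive`` is False when no positive window lies in-event.
    """
    times = np.asarray(times, dtype=np.float64)
    preds = np.asarray(preds, dtype=np.int64)
    if times.size == 0:
        raise ValueError("empty prediction sequence")
    # a window [t, t+w) is in-event when it overlaps [onset, offset)
    in_event = (times + window_s > event.onset_s + 1e-9) & (
        times < event.offset_s - 1e-9
    )
    if not in_event.any():
        raise ValueError(
            f"event {event.seizure_id} [{event.onset_s}, {event.offset_s}) "
            "outside the prediction span"
        )
    any_positive = bool((preds[in_event] == 1).any())
    delay = None
    for start, end, length in _positive_runs(times, preds, window_s):
        if length < run_len:
            continue
        if end > event.onset_s + 1e-9 and start < event.offset_s - 1e-9:
            delay = max(0.0, start - event.onset_s)
            break
    sub = delay is not None and delay > MAX_ACCEPTABLE_DELAY_S
    return EventDelay(event.seizure_id, delay, any_positive, sub)


def evaluate_events(
    pred,
    truth,
    times,
    ann: list[SeizureAnnotation],
    run_len: int = 2,
    window_s: float = 0.5,
    weights: ScoreWeights | None = None,
) -> EventMetrics:
    """Window confusion + per-event delay accounting.

    ``mean_dd_s`` averages over events with a qualifying detection run;
    ``undetected`` counts events with no positive window at all.
    """
    if not ann:
        raise ValueError("no seizure events to evaluate")
    accuracy, recall, precision, _, _ = window_confusion(pred, truth)
    per_event = [
        detection_delay(times, pred, a, run_len=run_len, window_s=window_s)
        for a in ann
    ]
    delays = [e.delay_s for e in per_event if e.delay_s is not None]
    mean_dd = float(np.mean(delays)) if delays else 0.0
    undetected = sum(1 for e in per_event if not e.any_positive)
    metrics = EventMetrics(
        accuracy=accuracy,
        recall=recall,
        precision=precision,
        mean_dd_s=mean_dd,
        undetected=undetected,
        n_seizures=len(ann),
        dd_flags=[e.seizure_id for e in per_event if e.suboptimal],
        per_event=per_event,
    )
    if weights is not None:
        metrics.score = composite_score(accuracy, mean_dd, recall, weights)
    return metrics


def composite_score(
    acc: float, mean_dd_s: float, recall: float, w: ScoreWeights
) -> float:
    """0-10 composite of accuracy, normalized delay, and recall."""
    if not (0.0 <= acc <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("acc and recall must lie in [0, 1]")
    if mean_dd_s < 0:
        raise ValueError("mean_dd_s must be nonnegative")
    delay_term = max(0.0, 1.0 - mean_dd_s / w.dd_norm_s)
    return w.scale * (w.alpha * acc + w.beta * delay_term + w.gamma * recall)
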