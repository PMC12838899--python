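"""Electrode-reduction experiments.

Three attribution routes:

* per-channel |Pearson r| between raw samples and the binary label,
* Shapley channel attribution (exact enumeration for small montages,
  permutation sampling otherwise),
* per-channel ictal/interictal band-power ratio (seizure-origin ranking).

Plus evaluation of predefined electrode subsets (``builtin_combos``)
through the full harmonize -> featurize -> train -> evaluate pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
from scipy import signal as sps

from ._pipeline import cohort_segments, run_split
from .bilstm_model import ModelConfig, monte_carlo_splits
from .eeg_io import harmonize_montage
from .event_eval import EventMetrics, ScoreWeights
from .featurize import FrameConfig
from .montage import canonical_sort_key, validate_labels

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChannelCombo:
    name: str
    electrodes: tuple[str, ...]
    selection_method: str  # "similarity" | "correlation-topK" | "manual"

    def __post_init__(self) -> None:
        labs = validate_labels(self.electrodes)
        if not labs:
            raise ValueError("combo must name at least one electrode")
        object.__setattr__(self, "electrodes", tuple(labs))


@dataclass
class ChannelScore:
    electrode: str
    correlation: float | None = None
    shapley: float | None = None
    band_power_ratio: float | None = None


def builtin_combos() -> dict[str, ChannelCombo]:
    """The five predefined electrode subsets."""
    return {
        "Common 15": ChannelCombo(
            "Common 15",
            ("C3", "C4", "CZ", "F3", "F4", "F7", "F8", "FP1", "FP2", "FZ",
             "O1", "O2", "P3", "P4", "PZ"),
            "manual",
        ),
        "Combo 1": ChannelCombo(
            "Combo 1", ("FP1", "FP2", "F7", "O1", "F3"), "similarity"
        ),
        "Combo 2": ChannelCombo(
            "Combo 2", ("FP1", "FP2", "F7", "O1", "F3", "FZ"), "similarity"
        ),
        "Combo 3": ChannelCombo(
            "Combo 3", ("O2", "O1", "F7", "PZ"), "correlation-topK"
        ),
        "Combo 4": ChannelCombo(
            "Combo 4", ("O2", "O1", "F7", "PZ", "C3", "CZ"), "correlation-topK"
        ),
    }


# ---------------------------------------------------------------------------
# Correlation ranking


def correlation_ranking(
    data: np.ndarray, labels: np.ndarray, channel_labels
) -> list[ChannelScore]:
    """|Pearson r| per channel vs the per-sample binary label, descending.

    Ties (and constant channels, which get r = 0 with a warning) are broken
    by canonical 10-20 ordering.
    """
    data = np.asarray(data, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if data.ndim != 2 or data.shape[1] != labels.size:
        raise ValueError("data must be channels x samples aligned with labels")
    if np.unique(labels).size < 2:
        raise ValueError("labels must contain both classes")
    y = labels - labels.mean()
    y_ss = float(y @ y)
    scores = []
    for ch, lab in zip(data, channel_labels):
        x = ch - ch.mean()
        x_ss = float(x @ x)
        if x_ss <= 0:
            logger.warning("channel %s is constant; correlation set to 0", lab)
            r = 0.0
        else:
            r = abs(float(x @ y) / np.sqrt(x_ss * y_ss))
        scores.append(ChannelScore(electrode=str(lab).upper(), correlation=r))
    scores.sort(key=lambda s: (-s.correlation, canonical_sort_key(s.electrode)))
    return scores


# ---------------------------------------------------------------------------
# Shapley attribution


def shapley_importance(
    value_fn,
    channels,
    n_perm: int = 500,
    seed: int = 0,
    exact: bool | None = None,
) -> list[ChannelScore]:
    """Shapley channel attribution for a set-valued performance function.

    ``value_fn(frozenset_of_channels) -> float``. Exact enumeration is
    used for <= 6 channels (or on request); otherwise the permutation-
    sampling estimator averages marginal contributions over ``n_perm``
    seeded random orderings.
    """
    channels = [str(c) for c in channels]
    n = len(channels)
    if n == 0:
        raise ValueError("no channels given")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if exact is None:
        exact = n <= 6

    cache: dict[frozenset, float] = {}

    def v(subset: frozenset) -> float:
        if subset not in cache:
            try:
                cache[subset] = float(value_fn(subset))
            except Exception as e:
                raise RuntimeError(
                    f"value function failed on subset {sorted(subset)}: {e}"
                ) from e
        return cache[subset]

    phi = dict.fromkeys(channels, 0.0)
    if exact:
        for order in permutations(channels):
            acc: frozenset = frozenset()
            for ch in order:
                phi[ch] += v(acc | {ch}) - v(acc)
                acc = acc | {ch}
        total = float(factorial(n))
        for ch in channels:
            phi[ch] /= total
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            order = [channels[i] for i in rng.permutation(n)]
            acc = frozenset()
            for ch in order:
                phi[ch] += v(acc | {ch}) - v(acc)
                acc = acc | {ch}
        for ch in channels:
            phi[ch] /= n_perm
    return [ChannelScore(electrode=ch, shapley=phi[ch]) for ch in channels]


# ---------------------------------------------------------------------------
# Seizure-origin (band-power) ranking and the surrogate value function


def band_power_ranking(
    rec, labels, band_hz: tuple[float, float] = (3.0, 5.0)
) -> list[ChannelScore]:
    """Per-channel ictal/interictal band-power ratio, descending."""
    lab = np.asarray(labels.labels, dtype=bool)
    if not lab.any() or lab.all():
        raise ValueError("need both ictal and interictal samples")
    scores = []
    for ch, name in zip(rec.data, rec.channel_labels):
        p_ict = _band_power(ch[lab], rec.fs, band_hz)
        p_int = _band_power(ch[~lab], rec.fs, band_hz)
        ratio = p_ict / p_int if p_int > 0 else np.inf
        scores.append(ChannelScore(electrode=name, band_power_ratio=float(ratio)))
    scores.sort(
        key=lambda s: (-s.band_power_ratio, canonical_sort_key(s.electrode))
    )
    return scores


def _band_power(x: np.ndarray, fs: float, band_hz: tuple[float, float]) -> float:
    nper = min(x.size, int(fs * 2))
    f, p = sps.welch(x, fs=fs, nperseg=nper)
    sel = (f >= band_hz[0]) & (f <= band_hz[1])
    return float(np.trapezoid(p[sel], f[sel]))


def surrogate_value_fn(
    rec, labels, cfg: FrameConfig, band_hz: tuple[float, float] = (1.0, 12.0),
    seed: int = 0,
):
    """Window-accuracy of a logistic model on per-channel window band power.

    A fast stand-in for full model retraining when scoring channel
    coalitions for Shapley attribution. ``value_fn(frozenset()) = max
    class prior`` (the best constant predictor).
    """
    from sklearn.linear_model import LogisticRegression

    W = cfg.window_len
    n_win = rec.n_samples // W
    x = rec.data[:, : n_win * W].reshape(rec.n_channels, n_win, W)
    power = np.log1p((x - x.mean(axis=2, keepdims=True)) ** 2).mean(axis=2)  # (C, n_win)
    y = (
        labels.labels[: n_win * W].reshape(n_win, W).mean(axis=1) >= cfg.label_rule
    ).astype(int)
    index = {lab: i for i, lab in enumerate(rec.channel_labels)}

    def value(subset) -> float:
        if not subset:
            return float(max(y.mean(), 1 - y.mean()))
        rows = [index[str(c).upper()] for c in subset]
        feats = power[rows].T
        clf = LogisticRegression(max_iter=200, random_state=seed)
        clf.fit(feats, y)
        return float(clf.score(feats, y))

    return value


# ---------------------------------------------------------------------------
# Combo evaluation


def evaluate_combo(
    cohort,
    combo: ChannelCombo,
    model_cfg: ModelConfig,
    frame_cfg: FrameConfig | None = None,
    run_len: int = 2,
    weights: ScoreWeights | None = None,
    seed: int = 0,
) -> EventMetrics:
    """Full pipeline on the reduced montage: harmonize -> featurize ->
    train -> event evaluation (single Monte Carlo split)."""
    frame_cfg = frame_cfg or FrameConfig()
    reduced = [
        (harmonize_montage(rec, combo.electrodes), anns) for rec, anns in cohort
    ]
    framed, anns = cohort_segments(reduced, frame_cfg, seed=seed)
    plan = monte_carlo_splits(anns, k=1, seed=seed)
    metrics, _ = run_split(
        framed, anns, plan.repeats[0][0], model_cfg,
        frame_cfg=frame_cfg, run_len=run_len, weights=weights,
    )
    return metrics
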