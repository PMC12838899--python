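"""BiLSTM sequence classifier: training protocol, Monte Carlo splits,
prediction, and outlier-aware retraining.

Training consumes packets (see :mod:`seizewin.featurize`) at either
*window* granularity (one step per 0.5 s frame) or *sample* granularity
(one step per raw sample, the window's wavelet block repeated across its
samples). Sequences are truncated into 0.5 s-aligned BPTT chunks
(default 10 s). Features are z-scored with statistics fit on the training
stream and stored with the model.

Prediction defaults to the causal mode that the streaming loop uses: the
forward direction runs over the whole past, the backward direction is
restarted inside the current 0.5 s window, so no decision uses future
samples. Full-bidirectional offline inference is available via
``causal=False``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._lstm import Adam, NetParams, LayerParams, bilstm_apply, init_params, loss_and_grads
from .eeg_io import SeizureAnnotation
from .featurize import Packet

SWEPT_LEARNING_RATES = (0.1, 0.01, 0.001, 0.0001)


@dataclass
class ModelConfig:
    hidden_sizes: tuple[int, ...] = (200,)
    learning_rate: float = 0.01
    epochs: int = 10
    batch: int = 8
    granularity: str = "sample"  # "sample" | "window"
    bptt_s: float = 10.0
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if not self.hidden_sizes or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be non-empty, all >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.granularity not in ("sample", "window"):
            raise ValueError("granularity must be 'sample' or 'window'")


@dataclass
class TrainedModel:
    config: ModelConfig
    params: NetParams
    feature_dim: int
    training_log: list[float] = field(default_factory=list)
    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mu) / self.sigma


@dataclass
class SplitPlan:
    k: int
    repeats: list[tuple[frozenset[str], frozenset[str]]]  # (train, test) ids
    seed: int


# ---------------------------------------------------------------------------
# Sequence extraction


def _packet_steps(packet: Packet, granularity: str) -> tuple[np.ndarray, np.ndarray]:
    if granularity == "window":
        return packet.frame_features, packet.frame_labels
    return packet.samples, packet.sample_labels


def _chunks(
    x: np.ndarray, y: np.ndarray, chunk_len: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    out = []
    for s in range(0, x.shape[0], chunk_len):
        xs, ys = x[s:s + chunk_len], y[s:s + chunk_len]
        if xs.shape[0] >= 2:
            out.append((xs, ys))
    return out


def _chunk_len(cfg: ModelConfig, packet: Packet) -> int:
    steps_per_window = 1 if cfg.granularity == "window" else packet.window_len
    n_windows = max(1, int(round(cfg.bptt_s / 0.5)))
    return n_windows * steps_per_window


# ---------------------------------------------------------------------------
# Training


def train_model(packets: list[Packet], cfg: ModelConfig) -> TrainedModel:
    if not packets:
        raise ValueError("no training packets")
    dims = {p.feature_dim for p in packets}
    if len(dims) != 1:
        raise ValueError(f"packets disagree on feature dimension: {sorted(dims)}")
    dim = dims.pop()

    rng = np.random.default_rng(cfg.seed)
    params = init_params(dim, cfg.hidden_sizes, 2, rng)
    model = TrainedModel(config=cfg, params=params, feature_dim=dim)
    _fit_standardizer(model, packets)
    _train_epochs(model, packets, cfg.epochs, rng)
    return model


def _fit_standardizer(model: TrainedModel, packets: list[Packet]) -> None:
    rows = np.concatenate(
        [_packet_steps(p, model.config.granularity)[0] for p in packets]
    )
    model.mu = rows.mean(axis=0)
    sd = rows.std(axis=0)
    model.sigma = np.where(sd > 1e-12, sd, 1.0)


def _train_epochs(
    model: TrainedModel,
    packets: list[Packet],
    epochs: int,
    rng: np.random.Generator,
) -> None:
    cfg = model.config
    seqs: list[tuple[np.ndarray, np.ndarray]] = []
    labels_seen: set[int] = set()
    for p in packets:
        x, y = _packet_steps(p, cfg.granularity)
        labels_seen |= set(np.unique(y).tolist())
        seqs.extend(_chunks(model.standardize(x), y.astype(np.int64),
                            _chunk_len(cfg, p)))
    if labels_seen != {0, 1}:
        raise ValueError(
            f"training stream must contain both classes, found {sorted(labels_seen)}"
        )

    flat = model.params.flat()
    opt = getattr(model, "_opt", None)
    if opt is None:
        opt = Adam([w.shape for w in flat], lr=cfg.learning_rate)
        model._opt = opt

    for _ in range(epochs):
        order = rng.permutation(len(seqs))
        # group equal-length chunks so they can share a batch
        by_len: dict[int, list[int]] = {}
        for idx in order:
            by_len.setdefault(seqs[idx][0].shape[0], []).append(int(idx))
        batches = []
        for idxs in by_len.values():
            for s in range(0, len(idxs), cfg.batch):
                batches.append(idxs[s:s + cfg.batch])
        rng.shuffle(batches)

        losses = []
        for batch in batches:
            x = np.stack([seqs[i][0] for i in batch], axis=1)  # (T,B,D)
            y = np.stack([seqs[i][1] for i in batch], axis=1)  # (T,B)
            loss, grads = loss_and_grads(model.params, x, y)
            opt.step(flat, grads)
            losses.append(loss)
        model.training_log.append(float(np.mean(losses)))


# ---------------------------------------------------------------------------
# Prediction


def predict_frames(
    model: TrainedModel, packet: Packet, causal: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window binary predictions and scores in [0, 1].

    At sample granularity each window's decision is the majority vote over
    its per-sample decisions; the score is the mean positive-class
    probability across the window.
    """
    if packet.feature_dim != model.feature_dim:
        raise ValueError(
            f"packet feature dim {packet.feature_dim} != model {model.feature_dim}"
        )
    cfg = model.config
    x, _ = _packet_steps(packet, cfg.granularity)
    block = 1 if cfg.granularity == "window" else packet.window_len
    probs = bilstm_apply(
        model.params,
        model.standardize(x)[:, None, :],
        causal_block=block if causal else None,
    )[:, 0, 1]
    if cfg.granularity == "window":
        scores = probs
        preds = (scores > cfg.threshold).astype(np.int8)
        return preds, scores
    W = packet.window_len
    per_win = probs.reshape(-1, W)
    votes = (per_win > cfg.threshold).sum(axis=1)
    preds = (votes > W // 2).astype(np.int8)  # strict majority of 128
    return preds, per_win.mean(axis=1)


# ---------------------------------------------------------------------------
# Monte Carlo splits


def monte_carlo_splits(
    anns: list[SeizureAnnotation], k: int = 5, seed: int = 0, ratio: float = 0.7
) -> SplitPlan:
    """Seizure-level shuffled train/test splits, repaired so that every
    patient keeps at least one training seizure in every repeat."""
    by_patient: dict[str, list[str]] = {}
    for a in anns:
        by_patient.setdefault(a.patient_id, []).append(a.seizure_id)
    for pid, sids in by_patient.items():
        if not sids:
            raise ValueError(f"patient {pid} has no seizures")
    all_ids = sorted(a.seizure_id for a in anns)
    rng = np.random.default_rng(seed)
    repeats = []
    for _ in range(k):
        perm = [all_ids[i] for i in rng.permutation(len(all_ids))]
        n_train = int(round(ratio * len(perm)))
        train = set(perm[:n_train])
        test = set(perm[n_train:])
        for pid, sids in sorted(by_patient.items()):
            if not any(s in train for s in sids):
                fix = sorted(sids)[0]
                test.discard(fix)
                train.add(fix)
        repeats.append((frozenset(train), frozenset(test)))
    return SplitPlan(k=k, repeats=repeats, seed=seed)


def split_packets(
    packets: list[Packet], train_ids: frozenset[str]
) -> tuple[list[Packet], list[Packet]]:
    """Partition packets by the seizures they contain.

    A packet goes to the training side iff every seizure it touches is a
    training seizure; packets mixing train and test seizures are dropped
    (they would leak test signal into training).
    """
    train, test = [], []
    for p in packets:
        sids = {s for s in p.seizure_ids if s is not None}
        if not sids or sids <= train_ids:
            train.append(p)
        elif not (sids & train_ids):
            test.append(p)
    return train, test


# ---------------------------------------------------------------------------
# Outlier-aware retraining


def find_outlier_seizures(
    model: TrainedModel, train_packets: list[Packet],
    ann: list[SeizureAnnotation] | None = None,
) -> set[str]:
    """Training seizures with zero positive-predicted windows in-event."""
    positives: dict[str, int] = {}
    for p in train_packets:
        preds, _ = predict_frames(model, p)
        for pred, sid in zip(preds, p.seizure_ids):
            if sid is None:
                continue
            positives[sid] = positives.get(sid, 0) + int(pred)
    if ann is not None:
        known = {a.seizure_id for a in ann}
        positives = {s: v for s, v in positives.items() if s in known}
    return {sid for sid, n_pos in positives.items() if n_pos == 0}


def retrain_with_outliers(
    model: TrainedModel,
    train_packets: list[Packet],
    outliers: set[str],
    cfg: ModelConfig | None = None,
    duplication: int = 3,
) -> TrainedModel:
    """Continue training with outlier-containing packets duplicated.

    Only training-split packets are consumed; passing a seizure id that is
    not present in the training packets raises, which guards against test
    leakage.
    """
    cfg = cfg or model.config
    train_sids = {s for p in train_packets for s in p.seizure_ids if s is not None}
    unknown = set(outliers) - train_sids
    if unknown:
        raise ValueError(
            f"outlier seizures not in the training packets: {sorted(unknown)}"
        )
    stream = list(train_packets)
    for p in train_packets:
        if any(s in outliers for s in p.seizure_ids if s is not None):
            stream.extend([p] * (duplication - 1))

    new = TrainedModel(
        config=cfg,
        params=_copy_params(model.params),
        feature_dim=model.feature_dim,
        training_log=list(model.training_log),
        mu=model.mu.copy(),
        sigma=model.sigma.copy(),
    )
    rng = np.random.default_rng((cfg.seed * 2654435761 + 17) % (2**32))
    _train_epochs(new, stream, cfg.epochs, rng)
    return new


def _copy_params(params: NetParams) -> NetParams:
    layers = [
        (
            LayerParams(f.W.copy(), f.U.copy(), f.b.copy()),
            LayerParams(b.W.copy(), b.U.copy(), b.b.copy()),
        )
        for f, b in params.layers
    ]
    return NetParams(layers, params.Wo.copy(), params.bo.copy())


# ---------------------------------------------------------------------------
# Checkpoint I/O


def save_model(model: TrainedModel, path) -> Path:
    path = Path(path)
    arrays: dict[str, np.ndarray] = {"mu": model.mu, "sigma": model.sigma,
                                     "Wo": model.params.Wo, "bo": model.params.bo}
    for li, (f, b) in enumerate(model.params.layers):
        for tag, lp in (("f", f), ("b", b)):
            arrays[f"l{li}{tag}_W"] = lp.W
            arrays[f"l{li}{tag}_U"] = lp.U
            arrays[f"l{li}{tag}_b"] = lp.b
    np.savez_compressed(path, **arrays)
    meta = {
        "hidden_sizes": list(model.config.hidden_sizes),
        "learning_rate": model.config.learning_rate,
        "epochs": model.config.epochs,
        "batch": model.config.batch,
        "granularity": model.config.granularity,
        "bptt_s": model.config.bptt_s,
        "threshold": model.config.threshold,
        "seed": model.config.seed,
        "feature_dim": model.feature_dim,
        "training_log": model.training_log,
    }
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def load_model(path) -> TrainedModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    cfg = ModelConfig(
        hidden_sizes=tuple(meta["hidden_sizes"]),
        learning_rate=meta["learning_rate"],
        epochs=meta["epochs"],
        batch=meta["batch"],
        granularity=meta["granularity"],
        bptt_s=meta["bptt_s"],
        threshold=meta["threshold"],
        seed=meta["seed"],
    )
    with np.load(path) as z:
        layers = []
        for li in range(len(cfg.hidden_sizes)):
            pair = tuple(
                LayerParams(z[f"l{li}{tag}_W"], z[f"l{li}{tag}_U"], z[f"l{li}{tag}_b"])
                for tag in ("f", "b")
            )
            layers.append(pair)
        params = NetParams(layers, z["Wo"], z["bo"])
        model = TrainedModel(
            config=cfg, params=params, feature_dim=int(meta["feature_dim"]),
            training_log=list(meta["training_log"]),
            mu=z["mu"].copy(), sigma=z["sigma"].copy(),
        )
    return model
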