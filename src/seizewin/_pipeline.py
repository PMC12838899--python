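"""Shared train/evaluate plumbing for experiments and combo evaluation.

Balanced segments are split at the seizure level *before* packetization:
each seizure's ictal segment and its matched interictal segment travel
together to the train or test side, and each side is packed into its own
5-minute packets. This keeps every packet pure with respect to the split.
"""

from __future__ import annotations

import numpy as np

from .bilstm_model import ModelConfig, TrainedModel, predict_frames, train_model
from .eeg_io import SeizureAnnotation, annotations_to_labels
from .event_eval import EventMetrics, ScoreWeights, evaluate_events, weighting_schemes
from .featurize import (
    FrameConfig,
    FramedSegment,
    balance_segments,
    frame_segments,
    packetize,
)


def cohort_segments(
    cohort, cfg: FrameConfig, seed: int = 0
) -> tuple[list[FramedSegment], list[SeizureAnnotation]]:
    """Balance and frame every recording of a cohort.

    Window times and annotation times are shifted onto a shared cohort
    clock (one recording after another with a large guard gap), so event
    evaluation can safely concatenate frames across recordings.
    """
    framed: list[FramedSegment] = []
    anns: list[SeizureAnnotation] = []
    offset = 0.0
    for i, (rec, rec_anns) in enumerate(cohort):
        labels = annotations_to_labels(rec_anns, rec.fs, rec.n_samples)
        segments = balance_segments(rec, rec_anns, labels, cfg, seed=seed + i)
        for fs_ in frame_segments(rec, labels, segments, cfg):
            for f in fs_.frames:
                f.t_start_s += offset
            fs_.segment.start_s += offset
            fs_.segment.end_s += offset
            framed.append(fs_)
        anns.extend(
            SeizureAnnotation(
                a.patient_id, a.seizure_id, a.onset_s + offset, a.offset_s + offset
            )
            for a in rec_anns
        )
        offset += rec.duration_s + 1000.0
    return framed, anns


def split_segments(
    framed: list[FramedSegment], train_ids: frozenset[str]
):
    train = [f for f in framed if f.segment.seizure_id in train_ids]
    test = [f for f in framed if f.segment.seizure_id not in train_ids]
    return train, test


def run_split(
    framed: list[FramedSegment],
    anns: list[SeizureAnnotation],
    train_ids: frozenset[str],
    model_cfg: ModelConfig,
    frame_cfg: FrameConfig | None = None,
    run_len: int = 2,
    weights: ScoreWeights | None = None,
) -> tuple[EventMetrics, TrainedModel]:
    """Train on the training-side segments, evaluate events on the rest."""
    frame_cfg = frame_cfg or FrameConfig()
    weights = weights or weighting_schemes()["W1"]
    train_seg, test_seg = split_segments(framed, train_ids)
    if not train_seg or not test_seg:
        raise ValueError("split leaves an empty train or test side")
    # shuffle segment order before packing: the deterministic
    # ictal/interictal alternation is otherwise a label leak that a
    # sequence model can exploit without reading the signal
    rng = np.random.default_rng(model_cfg.seed + 904_831)
    train_seg = [train_seg[i] for i in rng.permutation(len(train_seg))]
    test_seg = [test_seg[i] for i in rng.permutation(len(test_seg))]
    train_packets = packetize(train_seg, frame_cfg)
    test_packets = packetize(test_seg, frame_cfg)
    model = train_model(train_packets, model_cfg)

    preds, truth, times = [], [], []
    test_sids: set[str] = set()
    for p in test_packets:
        pw, _ = predict_frames(model, p)
        preds.append(pw)
        truth.append(p.frame_labels)
        times.append(p.frame_times)
        test_sids |= {s for s in p.seizure_ids if s is not None}
    test_anns = [a for a in anns if a.seizure_id in test_sids]
    metrics = evaluate_events(
        np.concatenate(preds),
        np.concatenate(truth),
        np.concatenate(times),
        test_anns,
        run_len=run_len,
        window_s=frame_cfg.window_s,
        weights=weights,
    )
    return metrics, model
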