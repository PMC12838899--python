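# seizewin

Windowed EEG seizure detection toolkit: wavelet-augmented 0.5 s feature
frames, balanced 5-minute training packets, a BiLSTM sequence classifier,
event-level evaluation with a composite accuracy/delay/recall score,
electrode-reduction analysis, and a causal streaming inference loop.
Every stage is exercisable end-to-end on synthetic EEG — no clinical data
required.

## What it does

1. **I/O & montage** (`seizewin.eeg_io`) — read/write recordings as CSV
   channel matrices, plain EDF, or a lossless `.npz` container; seizure
   annotations as CSV with 0.01 s precision; harmonize any montage to an
   ordered 10–20 subset.
2. **Synthetic EEG** (`seizewin.synth_eeg`) — deterministic multi-patient
   cohorts: 19-channel 10–20 montage at 256 Hz, 1/f background with
   alpha activity and blink artifacts, band-limited 3–5 Hz seizures of
   6–140 s (mean ≈ 60 s) with configurable amplitude and focus channels.
3. **Featurization** (`seizewin.featurize`) — non-overlapping 0.5 s
   windows; per step: C raw channel values + the arithmetic-mean channel
   + 134 single-level db4 wavelet coefficients of the window's mean
   channel (feature dimension C + 135, e.g. 141 for 6 electrodes, 154
   for 19). Seizure/non-seizure balancing by equal-duration interictal
   segment pairing, then 300 s packets of 600 frames.
4. **Model** (`seizewin.bilstm_model`) — a NumPy bidirectional LSTM
   stack with manual backprop and Adam (no deep-learning framework
   needed), trainable at window or per-sample granularity; seizure-level
   Monte Carlo splits with per-patient repair; outlier-seizure discovery
   and duplication-weighted retraining that provably never touches test
   data.
5. **Evaluation** (`seizewin.event_eval`) — window confusion metrics,
   per-event detection delay with run-length smoothing, undetected-event
   accounting, and the 0–10 composite score
   `10·[α·Acc + β·(1 − DD/13) + γ·Recall]` under six weighting schemes
   (W1 = 0.4/0.4/0.2); delays above 7.41 s are flagged.
6. **Channel selection** (`seizewin.channel_select`) — correlation
   ranking, band-power seizure-origin ranking, exact/sampled Shapley
   channel attribution, and evaluation of predefined reduced montages
   (Combos 1–4, Common 15).
7. **Streaming** (`seizewin.realtime_loop`) — causal window-by-window
   inference (forward state carried, backward direction confined to the
   current window) with per-stage latency accounting; stream and batch
   decisions are identical by construction.
8. **Experiments** (`seizewin.experiments_cli`) — architecture and
   electrode-reduction sweeps under Monte Carlo repetition, with
   self-consistent mean ± sd report tables (CSV + JSON).

## CLI

```bash
seizewin simulate  --out cohort/                  # synthetic cohort + manifest
seizewin convert   --in p000.csv --out p000.edf   # format conversion
seizewin featurize --rec p000.csv --ann p000_annotations.csv --out frames.npz
seizewin train     --frames frames.npz --hidden 64 --lr 0.01 \
                   --granularity window --out model.npz
seizewin predict   --model model.npz --frames frames.npz --out preds.npz
seizewin eval      --pred preds.npz --ann p000_annotations.csv \
                   --weights W1 --run-len 2 --out report.json
seizewin retrain   --model model.npz --frames frames.npz --outliers auto \
                   --out model2.npz
seizewin reduce    --cohort cohort/ --combo "Combo 2"
seizewin reduce    --cohort cohort/ --rank correlation
seizewin stream    --model model.npz --rec p000.csv --run-len 2
seizewin experiment --config exp.yaml --out results/
```

Stacked hidden layers are written `--hidden 200+100`.

## Notes

* The DWT is implemented in-package (db1/db2/db4, symmetric extension)
  and is numerically identical to `pywt.dwt(..., mode="symmetric")`;
  reference values are frozen in `tests/test_dwt.py`.
* Balanced segments are packed in seeded-shuffled order: a fixed
  ictal-then-interictal alternation is a positional label cue that a
  sequence model can exploit without reading the signal.
* Streaming latency targets (total < 0.5 s per window, classification
  < 0.1 s) are reported, never asserted — they are hardware-dependent.
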