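"""Synthetic multi-patient scalp EEG with embedded seizures.

Background activity is 1/f-weighted noise plus an alpha-band (8-12 Hz)
component, optionally contaminated by blink transients on the frontal
electrodes. Seizures are band-limited low-frequency oscillations (default
3-5 Hz) with a 1 s amplitude ramp at onset, added on a configurable set of
focus channels. Everything is a pure function of (config, seed).

These cohorts are desk-scale stand-ins for clinical recordings: minutes of
signal per patient, seizure durations bounded in [6, 140] s with mean ~60 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eeg_io import Recording, SeizureAnnotation, _round_grid
from .montage import CANONICAL_19


@dataclass
class SynthConfig:
    n_patients: int = 5
    seizures_per_patient: tuple[int, int] = (2, 3)  # inclusive range
    fs: float = 256.0
    channel_labels: tuple[str, ...] = CANONICAL_19
    recording_duration_s: float = 1200.0
    seizure_duration_s: tuple[float, float] = (6.0, 140.0)
    duration_mean_s: float = 60.0
    interictal_gap_s: float = 120.0
    background_amplitude: float = 20.0  # uV, 1/f noise scale
    alpha_amplitude: float = 8.0  # uV, 8-12 Hz component
    seizure_band_hz: tuple[float, float] = (3.0, 5.0)
    seizure_gain: float = 4.0  # ictal oscillation amplitude multiplier
    focus_channels: tuple[str, ...] | None = None  # None = all channels
    focus_weight_others: float = 0.0  # weight off the focus set
    artifact_rate: float = 2.0  # blinks per minute on FP1/FP2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        lo, hi = self.seizure_duration_s
        if not (6.0 <= lo < hi <= 140.0):
            raise ValueError("seizure duration bounds must satisfy 6 <= lo < hi <= 140")
        if not (lo <= self.duration_mean_s <= hi):
            raise ValueError("duration_mean_s outside the configured bounds")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if self.seizures_per_patient[0] < 1:
            raise ValueError("every patient needs at least one seizure")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def channel_weights(self) -> np.ndarray:
        if self.focus_channels is None:
            w = np.ones(self.n_channels)
        else:
            focus = {c.upper() for c in self.focus_channels}
            w = np.array(
                [1.0 if lab in focus else self.focus_weight_others
                 for lab in self.channel_labels]
            )
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("channel weights must be nonnegative, not all zero")
        return w


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                hp_hz: float = 0.5) -> np.ndarray:
    """1/f-weighted Gaussian noise, unit variance, AC-coupled.

    A soft high-pass at ``hp_hz`` mimics acquisition hardware and keeps
    ultra-slow drift from dominating window means.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    weight = np.zeros_like(freqs)
    weight[1:] = 1.0 / np.sqrt(freqs[1:])
    weight *= freqs / np.sqrt(freqs**2 + hp_hz**2)
    x = np.fft.irfft(spectrum * weight, n=n)
    sd = np.std(x)
    return x / sd if sd > 0 else x


def _blink(fs: float) -> np.ndarray:
    """A ~0.3 s smooth frontal deflection."""
    n = int(0.3 * fs)
    t = np.linspace(-1, 1, n)
    return np.exp(-4.0 * t**2)


def generate_background(
    duration_s: float, cfg: SynthConfig, seed: int
) -> np.ndarray:
    """Channel x sample matrix of non-ictal activity."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    out = np.empty((cfg.n_channels, n))
    for c in range(cfg.n_channels):
        pink = cfg.background_amplitude * _pink_noise(rng, n, cfg.fs)
        f_alpha = rng.uniform(8.0, 12.0)
        phase = rng.uniform(0, 2 * np.pi)
        alpha = cfg.alpha_amplitude * np.sin(2 * np.pi * f_alpha * t + phase)
        out[c] = pink + alpha

    if cfg.artifact_rate > 0:
        n_blinks = rng.poisson(cfg.artifact_rate * duration_s / 60.0)
        kernel = _blink(cfg.fs) * 6.0 * cfg.background_amplitude
        frontal = [i for i, lab in enumerate(cfg.channel_labels)
                   if lab in ("FP1", "FP2")]
        for _ in range(n_blinks):
            start = rng.integers(0, max(1, n - kernel.size))
            for c in frontal:
                out[c, start:start + kernel.size] += kernel
    return out


def _sample_duration(rng: np.random.Generator, cfg: SynthConfig) -> float:
    """Seizure duration on [lo, hi] with the configured mean (scaled Beta)."""
    lo, hi = cfg.seizure_duration_s
    m = (cfg.duration_mean_s - lo) / (hi - lo)
    a = 2.0
    b = a * (1.0 - m) / m
    return lo + (hi - lo) * rng.beta(a, b)


def _place_seizures(
    rng: np.random.Generator, cfg: SynthConfig, n_seizures: int
) -> list[tuple[float, float]]:
    durations = [_sample_duration(rng, cfg) for _ in range(n_seizures)]
    gap = cfg.interictal_gap_s
    needed = sum(durations) + gap * (n_seizures + 1)
    slack = cfg.recording_duration_s - needed
    if slack < 0:
        raise ValueError(
            f"{n_seizures} seizures (total {sum(durations):.0f} s) with "
            f"{gap:.0f} s gaps do not fit in {cfg.recording_duration_s:.0f} s"
        )
    # distribute the slack over the n+1 gaps via a random simplex point
    cuts = np.sort(rng.uniform(0, slack, size=n_seizures))
    extra = np.diff(np.concatenate([[0.0], cuts, [slack]]))
    intervals = []
    t = 0.0
    for d, e in zip(durations, extra):
        t += gap + e
        onset = _round_grid(t)
        offset = _round_grid(t + d)
        intervals.append((onset, offset))
        t += d
    return intervals


def _seizure_wave(
    rng: np.random.Generator, cfg: SynthConfig, n: int, fs: float
) -> np.ndarray:
    """Ictal oscillation with a 1 s onset amplitude ramp."""
    t = np.arange(n) / fs
    f0 = rng.uniform(*cfg.seizure_band_hz)
    phase = rng.uniform(0, 2 * np.pi)
    # slow frequency wobble keeps it band-limited but non-stationary
    wobble = 0.2 * np.sin(2 * np.pi * 0.1 * t + rng.uniform(0, 2 * np.pi))
    wave = np.sin(2 * np.pi * (f0 + wobble) * t + phase)
    ramp = np.clip(t, 0.0, 1.0)
    return wave * ramp


def generate_recording(
    cfg: SynthConfig, patient_id: str, seed: int
) -> tuple[Recording, list[SeizureAnnotation]]:
    rng = np.random.default_rng(seed)
    n_seiz = int(rng.integers(cfg.seizures_per_patient[0],
                              cfg.seizures_per_patient[1] + 1))
    intervals = _place_seizures(rng, cfg, n_seiz)

    data = generate_background(
        cfg.recording_duration_s, cfg, seed=int(rng.integers(0, 2**31))
    )
    weights = cfg.channel_weights()
    amp = cfg.seizure_gain * cfg.background_amplitude
    anns = []
    for k, (onset, offset) in enumerate(intervals):
        lo = int(round(onset * cfg.fs))
        hi = min(int(round(offset * cfg.fs)), data.shape[1])
        wave = _seizure_wave(rng, cfg, hi - lo, cfg.fs)
        data[:, lo:hi] += amp * weights[:, None] * wave[None, :]
        anns.append(
            SeizureAnnotation(
                patient_id=patient_id,
                seizure_id=f"{patient_id}_sz{k}",
                onset_s=onset,
                offset_s=offset,
            )
        )
    rec = Recording(
        patient_id=patient_id,
        channel_labels=list(cfg.channel_labels),
        data=data,
        fs=cfg.fs,
    )
    return rec, anns


def generate_cohort(
    cfg: SynthConfig,
) -> list[tuple[Recording, list[SeizureAnnotation]]]:
    """One recording per patient, seeded independently from ``cfg.seed``."""
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_patients)
    out = []
    for i, ss in enumerate(streams):
        pid = f"p{i:03d}"
        seed = int(ss.generate_state(1)[0])
        out.append(generate_recording(cfg, pid, seed))
    return out
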