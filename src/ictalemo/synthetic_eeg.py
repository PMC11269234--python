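"""Synthetic two-class EEG segment generator.

Emulates the statistical structure the classifier assumes: interictal
background is 1/f^beta colored noise with a low-amplitude 10 Hz
posterior-rhythm analog; ictal segments add a rhythmic spike-and-wave
train (default 3 Hz, the canonical generalized spike-wave rate) whose
amplitude is a controllable multiple of the background RMS. Each segment
draws from its own child RNG stream, split by segment index, so changing
the collection size never reshuffles earlier segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ictalemo.signal_io import EEGSegment, Label

#: Fraction of background RMS carried by the 10 Hz oscillation.
ALPHA_FRACTION = 0.5
#: Spike width in seconds (sharp biphasic transient of the spike-wave complex).
SPIKE_WIDTH_S = 0.070


@dataclass
class SynthConfig:
    """Parameters of the synthetic two-class collection.

    ictal_amplitude_ratio is the rhythmic spike-wave amplitude divided by
    the background RMS; the classes become exchangeable as it tends to 0.
    """

    n_per_class: int = 100
    fs: float = 200.0
    duration: float = 5.12
    ictal_amplitude_ratio: float = 4.0
    spike_wave_freq: float = 3.0
    noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.duration * self.fs < 64:
            raise ValueError("duration * fs must be >= 64 samples")
        if not self.ictal_amplitude_ratio > 0:
            raise ValueError("ictal_amplitude_ratio must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def _colored_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^beta, unit RMS, zero mean."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-beta / 2.0)
    scale[0] = 0.0  # zero mean
    x = np.fft.irfft(spec * scale, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _background_samples(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS-noise background plus a 10 Hz alpha-band oscillation."""
    n = cfg.n_samples
    noise = _colored_noise(n, cfg.noise_exponent, rng)
    t = np.arange(n) / cfg.fs
    phase = rng.uniform(0, 2 * np.pi)
    alpha = ALPHA_FRACTION * np.sqrt(2.0) * np.sin(2 * np.pi * 10.0 * t + phase)
    return noise + alpha


def _spike_wave_train(cfg: SynthConfig, n: int, phase_offset: float) -> np.ndarray:
    """Unit-amplitude spike-and-wave train at cfg.spike_wave_freq.

    Each cycle is one sharp biphasic raised-cosine spike (~70 ms) followed
    by a slow wave (one full mean-zero cycle) occupying the rest of the
    cycle, the classic generalized spike-wave morphology.
    """
    t = np.arange(n) / cfg.fs
    period = 1.0 / cfg.spike_wave_freq
    tau = np.mod(t + phase_offset * period, period)
    out = np.zeros(n)
    w = SPIKE_WIDTH_S
    in_spike = tau < w
    u = tau[in_spike] / w  # 0..1 across the spike
    # biphasic raised-cosine: positive lobe then negative lobe
    out[in_spike] = np.where(u < 0.5, 0.5 - 0.5 * np.cos(4 * np.pi * u), -(0.5 - 0.5 * np.cos(4 * np.pi * (u - 0.5))))
    slow = ~in_spike
    v = (tau[slow] - w) / (period - w)  # 0..1 across the slow wave
    # full mean-zero slow cycle: keeps the train AC-coupled and concentrates
    # power at the fundamental rather than at DC/harmonics
    out[slow] = 0.8 * np.sin(2 * np.pi * v)
    return out


def generate_background(cfg: SynthConfig, rng: np.random.Generator) -> EEGSegment:
    """One interictal (non-ictal) background segment."""
    x = _background_samples(cfg, rng)
    return EEGSegment(x, fs=cfg.fs, label=Label.NON_ICTAL, source_id="synthetic/background")


def generate_ictal(cfg: SynthConfig, rng: np.random.Generator) -> EEGSegment:
    """One ictal segment: background plus the scaled spike-wave train.

    The rhythmic component's amplitude is ictal_amplitude_ratio times the
    background RMS, so total energy strictly exceeds the background's.
    """
    bg = _background_samples(cfg, rng)
    bg_rms = np.sqrt(np.mean(bg**2))
    phase = rng.uniform(0, 1)
    train = _spike_wave_train(cfg, cfg.n_samples, phase)
    x = bg + cfg.ictal_amplitude_ratio * bg_rms * train
    return EEGSegment(x, fs=cfg.fs, label=Label.ICTAL, source_id="synthetic/ictal")


def generate_dataset(cfg: SynthConfig) -> list[EEGSegment]:
    """A class-balanced, deterministically ordered collection.

    Returns 2*n_per_class segments: all non-ictal first, then all ictal.
    Segment k of each class uses child stream k (non-ictal) or
    n_per_class+k (ictal) of the seed, so collections with different
    n_per_class share their common prefix per class.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(2 * cfg.n_per_class)
    segments: list[EEGSegment] = []
    for k in range(cfg.n_per_class):
        seg = generate_background(cfg, np.random.default_rng(children[k]))
        seg.source_id = f"synthetic/background#{k}"
        segments.append(seg)
    for k in range(cfg.n_per_class):
        seg = generate_ictal(cfg, np.random.default_rng(children[cfg.n_per_class + k]))
        seg.source_id = f"synthetic/ictal#{k}"
        segments.append(seg)
    return segments


def plant_noise_columns(values: np.ndarray, labels: np.ndarray, n_keep: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Keep the ``n_keep`` most class-separating columns; scramble the rest.

    Utility for controlled feature-selection experiments: the columns with
    the largest standardized class-mean difference keep their values, and
    every other column is independently row-permuted, destroying its
    association with the labels while preserving its marginal
    distribution. Returns (new matrix, indices of the kept columns).
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    pos = values[labels == 1]
    neg = values[labels == 0]
    sd = values.std(axis=0)
    sd[sd == 0] = 1.0
    score = np.abs(pos.mean(axis=0) - neg.mean(axis=0)) / sd
    keep = np.sort(np.argsort(score)[::-1][:n_keep])
    out = values.copy()
    mask = np.ones(values.shape[1], dtype=bool)
    mask[keep] = False
    for j in np.where(mask)[0]:
        out[:, j] = out[rng.permutation(values.shape[0]), j]
    return out, keep
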