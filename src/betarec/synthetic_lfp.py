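"""Synthetic local field potential (LFP) trial generator.

Emulates the statistical structure of single-channel dlPFC recordings
around sample onset in a recognition-memory task: a transient alpha/low-beta
(10-15 Hz) power increase that peaks shortly after onset and decays back to
baseline — larger and faster-decaying on trials followed by a correct
("hit") recognition choice than on miss trials — superimposed on 1/f
background noise with optional 50-Hz line contamination and harmonics.

Each trial consists of an epoch spanning at least -1000..+1000 ms around
sample onset plus a separate 1000-ms intertrial-interval baseline segment
containing background noise only (used downstream for RMS normalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BurstSpec", "NoiseConfig", "LFPTrialSet", "generate_trials"]


@dataclass
class BurstSpec:
    """Stimulus-evoked narrow-band burst, parameterized per trial label.

    The burst carrier frequency is drawn uniformly in ``band``.  Its
    envelope is zero before sample onset, rises linearly to
    ``peak_latency_ms`` and then decays exponentially with time constant
    ``decay_tau_ms``.  Hit trials default to a larger amplitude and a
    faster (smaller-tau) decay than miss trials, the two features the
    spectral and gradient stages are designed to detect.
    """

    band: tuple = (10.0, 15.0)
    amplitude: dict = field(default_factory=lambda: {"hit": 2.0, "miss": 1.0})
    peak_latency_ms: dict = field(default_factory=lambda: {"hit": 100.0, "miss": 100.0})
    decay_tau_ms: dict = field(default_factory=lambda: {"hit": 120.0, "miss": 300.0})

    def __post_init__(self):
        if not self.band[0] < self.band[1]:
            raise ValueError("band must satisfy f_lo < f_hi")
        if any(a < 0 for a in self.amplitude.values()):
            raise ValueError("amplitudes must be >= 0")
        if any(t <= 0 for t in self.decay_tau_ms.values()):
            raise ValueError("decay time constants must be > 0")


@dataclass
class NoiseConfig:
    """Background-noise parameters: 1/f^exponent floor plus line components."""

    amplitude: float = 1.0
    exponent: float = 1.0
    line_freqs: tuple = ()  # e.g. (50.0, 100.0, 150.0)
    line_amplitude: float = 0.5


@dataclass
class LFPTrialSet:
    """Labelled LFP trial epochs plus matched baseline segments."""

    trials: np.ndarray  # (n_trials, n_samples)
    fs: float
    onset_index: int
    labels: np.ndarray  # "hit" | "miss" per trial
    baselines: np.ndarray  # (n_trials, fs-worth of 1000 ms)
    truth: dict = field(default_factory=dict)

    @property
    def times_ms(self) -> np.ndarray:
        n = self.trials.shape[1]
        return (np.arange(n) - self.onset_index) * 1000.0 / self.fs


def _one_over_f_noise(
    shape: tuple, exponent: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Spectrally shaped Gaussian noise with power ~ 1/f**exponent."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    if exponent == 0:
        return white
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * scale, n=n, axis=-1)
    # keep unit variance so noise amplitude is interpretable
    return shaped / shaped.std(axis=-1, keepdims=True)


def generate_trials(
    n_hit: int,
    n_miss: int,
    burst: BurstSpec | None = None,
    noise: NoiseConfig | None = None,
    fs: float = 1000.0,
    epoch_ms: tuple = (-1000.0, 1000.0),
    baseline_ms: float = 1000.0,
    rng: np.random.Generator | int | None = None,
) -> LFPTrialSet:
    """Generate labelled LFP trials around sample onset.

    Defaults follow the recorded protocol: 1 kHz sampling, epochs from
    -1000 to +1000 ms around onset, a separate 1000-ms intertrial-interval
    baseline per trial.  A 30-kHz ``fs`` is supported purely to exercise
    the downsampling stage.
    """
    burst = burst if burst is not None else BurstSpec()
    noise = noise if noise is not None else NoiseConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if n_hit < 0 or n_miss < 0:
        raise ValueError("trial counts must be >= 0")
    if fs < 2.5 * burst.band[1]:
        raise ValueError(
            f"fs {fs} Hz too low for burst band up to {burst.band[1]} Hz "
            f"(need >= {2.5 * burst.band[1]} Hz)"
        )

    n_trials = n_hit + n_miss
    labels = np.array(["hit"] * n_hit + ["miss"] * n_miss)
    n_samp = int(round((epoch_ms[1] - epoch_ms[0]) * fs / 1000.0)) + 1
    n_base = int(round(baseline_ms * fs / 1000.0))
    onset_index = int(round(-epoch_ms[0] * fs / 1000.0))
    t_ms = (np.arange(n_samp) - onset_index) * 1000.0 / fs

    trials = noise.amplitude * _one_over_f_noise(
        (n_trials, n_samp), noise.exponent, fs, rng
    ) if noise.amplitude > 0 else np.zeros((n_trials, n_samp))
    baselines = noise.amplitude * _one_over_f_noise(
        (n_trials, n_base), noise.exponent, fs, rng
    ) if noise.amplitude > 0 else np.zeros((n_trials, n_base))

    for f_line in noise.line_freqs:
        phase = rng.uniform(0, 2 * np.pi, size=(n_trials, 1))
        trials += noise.line_amplitude * np.sin(
            2 * np.pi * f_line * t_ms[None, :] / 1000.0 + phase
        )
        tb = np.arange(n_base) / fs
        baselines += noise.line_amplitude * np.sin(
            2 * np.pi * f_line * tb[None, :] + phase
        )

    carriers = rng.uniform(burst.band[0], burst.band[1], size=n_trials)
    phases = rng.uniform(0, 2 * np.pi, size=n_trials)
    for i in range(n_trials):
        lab = labels[i]
        amp = burst.amplitude[lab]
        if amp == 0:
            continue
        peak = burst.peak_latency_ms[lab]
        tau = burst.decay_tau_ms[lab]
        env = np.zeros(n_samp)
        rising = (t_ms >= 0) & (t_ms < peak)
        env[rising] = t_ms[rising] / peak
        decaying = t_ms >= peak
        env[decaying] = np.exp(-(t_ms[decaying] - peak) / tau)
        trials[i] += amp * env * np.sin(
            2 * np.pi * carriers[i] * t_ms / 1000.0 + phases[i]
        )

    return LFPTrialSet(
        trials=trials,
        fs=fs,
        onset_index=onset_index,
        labels=labels,
        baselines=baselines,
        truth={
            "burst": burst,
            "noise": noise,
            "carriers": carriers,
            "n_hit": n_hit,
            "n_miss": n_miss,
        },
    )
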