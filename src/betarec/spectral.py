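"""Preprocessing and Morlet time-frequency decomposition.

The preprocessing chain mirrors standard LFP practice: second-order IIR
notch filters remove mains contamination (50 Hz and harmonics), the signal
is decimated to 1 kHz with zero-phase anti-aliasing, and each epoch is
divided by the root-mean-square of its intertrial-interval baseline so that
power is expressed in baseline-RMS units.

Power is then estimated by convolution with complex Morlet wavelets on an
integer frequency grid (8-60 Hz in 1-Hz steps by default, 53 frequencies).
Samples within half a wavelet of either epoch edge are flagged invalid
rather than padded, which is why analyses downstream restrict 1000-ms
epochs to 800-ms windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

__all__ = [
    "TimeFrequencyMap",
    "default_freqs",
    "preprocess",
    "baseline_normalize",
    "morlet_tfr",
    "tfr_stack",
]


def default_freqs() -> np.ndarray:
    """The default analysis grid: 8..60 Hz in steps of 1 Hz (53 values)."""
    return np.arange(8.0, 61.0, 1.0)


@dataclass
class TimeFrequencyMap:
    """Baseline-normalized power on a frequency x time grid.

    ``valid`` marks samples at least half a wavelet away from both epoch
    edges; margin samples carry power values but should not enter
    statistics.
    """

    power: np.ndarray  # (n_freqs, n_times), >= 0
    freqs: np.ndarray
    times_ms: np.ndarray
    valid: np.ndarray  # boolean, same shape as power
    label: str = ""

    def __post_init__(self):
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    def window(self, t_lo_ms: float, t_hi_ms: float) -> np.ndarray:
        """Boolean time mask for times in [t_lo_ms, t_hi_ms)."""
        return (self.times_ms >= t_lo_ms) & (self.times_ms < t_hi_ms)


def preprocess(
    x: np.ndarray,
    fs_in: float,
    notch_freqs=(50.0, 100.0, 150.0),
    fs_out: float = 1000.0,
    q: float = 30.0,
) -> np.ndarray:
    """Notch-filter mains components and decimate with zero-phase filtering.

    Applies a second-order IIR notch (quality factor ``q``) at each listed
    frequency, forward-backward so the output is phase-neutral, then
    resamples to ``fs_out`` through a polyphase anti-aliasing filter.
    Works on a single trace or a (n_trials, n_samples) stack.
    """
    if fs_in < fs_out:
        raise ValueError(f"fs_in {fs_in} < fs_out {fs_out}")
    for f0 in notch_freqs or ():
        if f0 >= fs_out / 2:
            raise ValueError(f"notch at {f0} Hz is above output Nyquist {fs_out / 2}")
    y = np.asarray(x, dtype=float)
    for f0 in notch_freqs or ():
        b, a = sps.iirnotch(f0, q, fs=fs_in)
        y = sps.filtfilt(b, a, y, axis=-1)
    if fs_in != fs_out:
        frac = Fraction(fs_out / fs_in).limit_denominator(1000)
        y = sps.resample_poly(y, frac.numerator, frac.denominator, axis=-1)
    return y


def baseline_normalize(x: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Divide a trace by the root-mean-square of its baseline segment."""
    baseline = np.asarray(baseline, dtype=float)
    if baseline.size == 0:
        raise ValueError("baseline segment is empty")
    rms = np.sqrt(np.mean(baseline**2))
    if rms == 0:
        raise ValueError("baseline is all zero; RMS division undefined")
    return np.asarray(x, dtype=float) / rms


def _morlet_wavelet(freq: float, fs: float, n_cycles: float) -> np.ndarray:
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    # gain scaled so a sine of amplitude a yields power ~ a^2 at its frequency
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    return 2.0 * w / (sigma_t * fs * np.sqrt(2.0 * np.pi))


def morlet_tfr(
    x: np.ndarray,
    fs: float,
    freqs=None,
    n_cycles: float = 7.0,
    onset_index: int = 0,
    label: str = "",
) -> TimeFrequencyMap:
    """Complex-Morlet power of a single trace on a frequency grid.

    Each wavelet has ``n_cycles`` cycles (fixed across frequencies), so
    temporal resolution scales with 1/frequency.  Power is the squared
    magnitude of the convolution.  Times are reported relative to
    ``onset_index``.
    """
    x = np.asarray(x, dtype=float)
    freqs = default_freqs() if freqs is None else np.asarray(freqs, dtype=float)
    if freqs.max() >= fs / 2:
        raise ValueError(f"max frequency {freqs.max()} Hz >= Nyquist {fs / 2} Hz")
    n = x.shape[-1]
    power = np.empty((len(freqs), n))
    valid = np.zeros((len(freqs), n), dtype=bool)
    for i, f in enumerate(freqs):
        w = _morlet_wavelet(f, fs, n_cycles)
        half = len(w) // 2
        if len(w) > n:
            raise ValueError(
                f"signal ({n} samples) shorter than the {f}-Hz wavelet ({len(w)})"
            )
        conv = sps.fftconvolve(x, w, mode="same")
        power[i] = np.abs(conv) ** 2
        valid[i, half : n - half] = True
    times_ms = (np.arange(n) - onset_index) * 1000.0 / fs
    return TimeFrequencyMap(
        power=power, freqs=freqs, times_ms=times_ms, valid=valid, label=label
    )


def tfr_stack(
    trials: np.ndarray,
    fs: float,
    freqs=None,
    n_cycles: float = 7.0,
    onset_index: int = 0,
) -> tuple:
    """Morlet power for a (n_trials, n_samples) stack.

    Returns ``(power, freqs, times_ms, valid)`` with power shaped
    (n_trials, n_freqs, n_times).  Convolutions are batched per frequency
    across trials.
    """
    trials = np.asarray(trials, dtype=float)
    freqs = default_freqs() if freqs is None else np.asarray(freqs, dtype=float)
    if freqs.max() >= fs / 2:
        raise ValueError(f"max frequency {freqs.max()} Hz >= Nyquist {fs / 2} Hz")
    n_trials, n = trials.shape
    power = np.empty((n_trials, len(freqs), n))
    valid = np.zeros((len(freqs), n), dtype=bool)
    for i, f in enumerate(freqs):
        w = _morlet_wavelet(f, fs, n_cycles)
        half = len(w) // 2
        if len(w) > n:
            raise ValueError(
                f"signal ({n} samples) shorter than the {f}-Hz wavelet ({len(w)})"
            )
        conv = sps.fftconvolve(trials, w[None, :], mode="same", axes=-1)
        power[:, i, :] = np.abs(conv) ** 2
        valid[i, half : n - half] = True
    times_ms = (np.arange(n) - onset_index) * 1000.0 / fs
    return power, freqs, times_ms, valid
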