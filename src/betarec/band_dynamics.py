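"""Band-averaged power dynamics, post-peak gradients and frequency selection.

After sample onset the alpha/low-beta (10-15 Hz) power rises transiently
and returns to baseline; the steepness of that post-peak return ("the
gradient") differs between subsequently remembered (hit) and forgotten
(miss) trials.  Gradients are estimated by ordinary least squares on each
integer frequency row of the trial-averaged spectrogram over a 150-ms
window starting at the detected band peak, then compared between labels
with a paired t test across the in-band frequencies (6 frequencies for
10-15 Hz, hence 5 degrees of freedom).

The stimulation frequency for the downstream rTMS experiment is the
midpoint of the intersection of the significant bands found in each
subject (10-17 Hz and 8-15 Hz intersect at 10-15 Hz, midpoint 12.5 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from betarec.spectral import TimeFrequencyMap

__all__ = [
    "BandSummary",
    "PairedTResult",
    "band_average",
    "peak_latency",
    "per_frequency_gradients",
    "paired_t",
    "select_stim_frequency",
    "band_summary",
]


@dataclass
class PairedTResult:
    """Classical paired t test: statistic, df = n - 1, two-tailed p."""

    t: float
    df: int
    p: float
    mean_diff: float


@dataclass
class BandSummary:
    band: tuple
    timecourse: dict  # label -> 1D band-mean power vs time
    times_ms: np.ndarray
    peak_latency_ms: dict  # label -> ms
    slopes: dict  # label -> slope per integer in-band frequency (power/ms)
    window_ms: dict  # label -> (start, end) of fitted segment
    slope_unit: str = "baseline-normalized power per ms"
    comparison: PairedTResult | None = None


def _band_rows(freqs: np.ndarray, band) -> np.ndarray:
    lo, hi = band
    if lo > hi:
        raise ValueError(f"band must satisfy f_lo <= f_hi, got {band}")
    rows = (freqs >= lo) & (freqs <= hi)
    if not rows.any():
        raise ValueError(f"band {band} contains no grid frequencies")
    return rows


def band_average(power: np.ndarray, freqs: np.ndarray, band) -> np.ndarray:
    """Mean over in-band frequency rows (and over trials if stacked).

    Accepts a (n_freqs, n_times) map or an (n_trials, n_freqs, n_times)
    stack; trials are averaged after the frequency mean.
    """
    power = np.asarray(power, dtype=float)
    rows = _band_rows(np.asarray(freqs), band)
    course = power[..., rows, :].mean(axis=-2)
    if course.ndim == 2:
        course = course.mean(axis=0)
    return course


def peak_latency(
    timecourse: np.ndarray, times_ms: np.ndarray, search_window_ms=(0.0, 400.0)
) -> float:
    """Time of the maximum within a search window; ties take the earliest."""
    timecourse = np.asarray(timecourse, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    sel = (times_ms >= search_window_ms[0]) & (times_ms <= search_window_ms[1])
    if not sel.any():
        raise ValueError(f"search window {search_window_ms} outside data range")
    seg = timecourse[sel]
    return float(times_ms[sel][np.argmax(seg)])


def per_frequency_gradients(
    tfr: TimeFrequencyMap, band, window_ms
) -> np.ndarray:
    """OLS slope (power per ms) of each integer in-band frequency row.

    The fit window must lie wholly inside the wavelet-valid region of the
    map; windows touching the edge margin are rejected rather than
    silently truncated.
    """
    rows = _band_rows(tfr.freqs, band)
    tsel = tfr.window(window_ms[0], window_ms[1])
    if not tsel.any():
        raise ValueError(f"window {window_ms} outside the map's time range")
    if not tfr.valid[np.ix_(rows, tsel)].all():
        raise ValueError(
            f"window {window_ms} overlaps the invalid wavelet margin"
        )
    t = tfr.times_ms[tsel]
    slopes = []
    for row in tfr.power[rows][:, tsel]:
        slope, _ = np.polyfit(t, row, 1)
        slopes.append(slope)
    return np.asarray(slopes)


def paired_t(x, y) -> PairedTResult:
    """Paired-sample t test on matched observations (two-tailed)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"need equal-length 1D vectors, got {x.shape}, {y.shape}")
    if len(x) < 2:
        raise ValueError("paired t test needs at least 2 pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0):
        if np.allclose(d, 0):
            # identical pairs: no difference, by convention t = 0, p = 1
            return PairedTResult(t=0.0, df=len(x) - 1, p=1.0, mean_diff=0.0)
        raise ValueError("zero variance of nonzero paired differences; t undefined")
    res = stats.ttest_rel(x, y)
    return PairedTResult(
        t=float(res.statistic),
        df=len(x) - 1,
        p=float(res.pvalue),
        mean_diff=float(d.mean()),
    )


def select_stim_frequency(band_a, band_b) -> float:
    """Midpoint of the intersection of two frequency bands (Hz)."""
    lo = max(band_a[0], band_b[0])
    hi = min(band_a[1], band_b[1])
    if lo > hi:
        raise ValueError(f"bands {band_a} and {band_b} do not overlap")
    return (lo + hi) / 2.0


def band_summary(
    tfr_by_label: dict,
    band=(10.0, 15.0),
    window_length_ms: float = 150.0,
    search_window_ms=(0.0, 400.0),
    fixed_window_ms=None,
    compare: tuple = ("hit", "miss"),
) -> BandSummary:
    """Full band-dynamics analysis over label-wise trial-averaged maps.

    For each label: band-average timecourse, peak latency, then OLS slopes
    over [peak, peak + window_length_ms] (or ``fixed_window_ms`` if given)
    for every integer in-band frequency.  If both labels in ``compare``
    are present, their slope vectors are compared with a paired t test.
    """
    timecourse, peaks, slopes, windows = {}, {}, {}, {}
    times_ms = None
    for label, tfr in tfr_by_label.items():
        times_ms = tfr.times_ms
        course = band_average(tfr.power, tfr.freqs, band)
        timecourse[label] = course
        peaks[label] = peak_latency(course, tfr.times_ms, search_window_ms)
        win = tuple(fixed_window_ms) if fixed_window_ms is not None else (
            peaks[label], peaks[label] + window_length_ms
        )
        windows[label] = win
        slopes[label] = per_frequency_gradients(tfr, band, win)
    comparison = None
    a, b = compare
    if a in slopes and b in slopes:
        comparison = paired_t(slopes[a], slopes[b])
    return BandSummary(
        band=tuple(band),
        timecourse=timecourse,
        times_ms=times_ms,
        peak_latency_ms=peaks,
        slopes=slopes,
        window_ms=windows,
        comparison=comparison,
    )
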