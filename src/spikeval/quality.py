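"""Per-unit quality metrics: SNR, firing rate, and ISI-violation ratio.

SNR is computed on the bandpass-filtered trace.  The filter multiplies each
channel's spectrum by the real, zero-phase gain

    A(f) = 1/2 * sqrt(1 + erf((f - fmin)/w_lo)) * sqrt(1 - erf((f - fmax)/w_hi))

evaluated at |f| (defaults fmin=300 Hz, fmax=6000 Hz, roll-off widths
w_lo=100 Hz and w_hi=1000 Hz), giving unit gain in the passband.  Noise is the
median absolute deviation of the filtered trace divided by 0.6745 — a robust
estimate of the Gaussian noise standard deviation.  SNR is the peak absolute
amplitude of the unit's average filtered spike waveform divided by the noise
estimate on the channel where that peak occurs.

The ISI-violation ratio divides the observed number of inter-spike intervals
below the refractory threshold (2.5 ms) by the number expected for a Poisson
train of the same rate: each of the N-1 intervals falls below t_ref with
probability 1 - exp(-lambda * t_ref), lambda = N / duration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq
from scipy.special import erf

from .mda import Firings, Recording

__all__ = [
    "FilterSpec",
    "UnitQuality",
    "filter_gain",
    "bandpass_filter",
    "estimate_noise",
    "average_waveform",
    "compute_snr",
    "isi_violation_ratio",
    "compute_unit_quality",
    "compute_quality_table",
]

MAD_TO_SD = 0.6745  #: MAD of a standard normal distribution
DEFAULT_REFRACTORY_MS = 2.5


@dataclass(frozen=True)
class FilterSpec:
    """Bandpass edges and erf roll-off widths, all in Hz."""

    fmin: float = 300.0
    fmax: float = 6000.0
    low_width: float = 100.0
    high_width: float = 1000.0

    def __post_init__(self):
        if not (0 < self.fmin < self.fmax):
            raise ValueError("need 0 < fmin < fmax")
        if self.low_width <= 0 or self.high_width <= 0:
            raise ValueError("roll-off widths must be positive")


@dataclass(frozen=True)
class UnitQuality:
    snr: float
    firing_rate: float
    isi_violation_ratio: float
    num_events: int
    peak_channel: int


def filter_gain(freqs, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Evaluate the bandpass gain A(|f|)."""
    f = np.abs(np.asarray(freqs, dtype=np.float64))
    lo = np.sqrt(0.5 * (1.0 + erf((f - spec.fmin) / spec.low_width)))
    hi = np.sqrt(0.5 * (1.0 - erf((f - spec.fmax) / spec.high_width)))
    return lo * hi


def bandpass_filter(recording: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Zero-phase bandpass via one full-length FFT per channel."""
    if recording.num_samples < 2:
        raise ValueError("recording must have at least 2 samples")
    n = recording.num_samples
    gain = filter_gain(rfftfreq(n, d=1.0 / recording.sample_rate), spec)
    spectra = rfft(recording.traces, axis=1)
    spectra *= gain
    filtered = irfft(spectra, n=n, axis=1).astype(recording.traces.dtype, copy=False)
    return Recording(filtered, recording.sample_rate, recording.geometry)


def estimate_noise(filtered_channel: np.ndarray) -> float:
    """Robust noise SD: median absolute deviation / 0.6745."""
    x = np.asarray(filtered_channel, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples to estimate noise")
    return float(np.median(np.abs(x - np.median(x))) / MAD_TO_SD)


def default_window(sample_rate: float) -> tuple[int, int]:
    """Waveform clip window: 1 ms before to 2 ms after the event."""
    return round(1e-3 * sample_rate), round(2e-3 * sample_rate)


def average_waveform(
    recording: Recording,
    event_times: np.ndarray,
    window: Optional[tuple[int, int]] = None,
) -> tuple[np.ndarray, int]:
    """Mean spike clip over events.

    Clips span ``[t - w_pre, t + w_post)`` around the floored event sample.
    Events whose clip crosses a recording boundary are dropped.  Returns the
    channels x (w_pre + w_post) mean waveform and the number of events used.
    """
    if window is None:
        window = default_window(recording.sample_rate)
    w_pre, w_post = window
    # firings times are 1-based; convert to 0-based sample indices
    t = np.floor(np.asarray(event_times, dtype=np.float64)).astype(np.int64) - 1
    ok = (t - w_pre >= 0) & (t + w_post <= recording.num_samples)
    t = t[ok]
    if len(t) == 0:
        raise ValueError("no events fully inside the recording")
    acc = np.zeros((recording.num_channels, w_pre + w_post), dtype=np.float64)
    for ti in t:
        acc += recording.traces[:, ti - w_pre : ti + w_post]
    return acc / len(t), len(t)


def compute_snr(
    recording: Recording,
    event_times: np.ndarray,
    spec: FilterSpec = FilterSpec(),
    already_filtered: bool = False,
) -> tuple[float, int]:
    """SNR of one unit and the channel where its waveform peak occurs."""
    filtered = recording if already_filtered else bandpass_filter(recording, spec)
    waveform, _ = average_waveform(filtered, event_times)
    peak_channel, _ = np.unravel_index(np.argmax(np.abs(waveform)), waveform.shape)
    peak = float(np.max(np.abs(waveform)))
    noise = estimate_noise(filtered.traces[peak_channel])
    if noise == 0.0:
        return float("inf"), int(peak_channel)
    return peak / noise, int(peak_channel)


def isi_violation_ratio(
    event_times_s: np.ndarray,
    duration_s: float,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
) -> float:
    """Observed refractory violations over the Poisson-expected count.

    NaN when fewer than 2 events.
    """
    t = np.sort(np.asarray(event_times_s, dtype=np.float64))
    n = len(t)
    if n < 2:
        return float("nan")
    t_ref = refractory_ms / 1000.0
    violations = int(np.count_nonzero(np.diff(t) < t_ref))
    lam = n / duration_s
    expected = (n - 1) * (1.0 - np.exp(-lam * t_ref))
    return violations / expected


def compute_unit_quality(
    recording: Recording,
    firings: Firings,
    unit_label: int,
    spec: FilterSpec = FilterSpec(),
    already_filtered: bool = False,
) -> UnitQuality:
    """SNR, firing rate, and ISI-violation ratio for one unit."""
    times = firings.times_for(unit_label)
    if len(times) == 0:
        raise ValueError(f"unit {unit_label} not present in firings")
    snr, peak_channel = compute_snr(
        recording, times, spec, already_filtered=already_filtered
    )
    duration = recording.duration
    return UnitQuality(
        snr=snr,
        firing_rate=len(times) / duration,
        isi_violation_ratio=isi_violation_ratio(times / recording.sample_rate, duration),
        num_events=len(times),
        peak_channel=peak_channel,
    )


def compute_quality_table(
    recording: Recording, firings: Firings, spec: FilterSpec = FilterSpec()
) -> dict[int, UnitQuality]:
    """Quality metrics for every unit, filtering the recording once."""
    filtered = bandpass_filter(recording, spec)
    return {
        int(l): compute_unit_quality(filtered, firings, int(l), spec, already_filtered=True)
        for l in firings.unit_labels
    }
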