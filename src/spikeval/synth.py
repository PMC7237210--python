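"""Synthetic ground-truth recordings and controlled pseudo-sortings.

The generator emulates the phenomenological simulation style used for
benchmark study sets: smooth biphasic waveform templates placed at random
source positions near the electrode array, inserted at Poisson firing times
(thinned to respect a refractory gap), each event scaled by a Gamma-distributed
amplitude factor with mean one, on top of iid Gaussian noise.  Optional
electrode drift moves each unit's source along the array over time; per-event
channel amplitudes are then re-derived by Gaussian-kernel interpolation over a
dense 0.5 um virtual grid, mimicking how drifting recordings are produced by
vertically shifting electrode positions.

``perturb_sorting`` degrades a ground-truth firings table in controlled ways
(deletions, insertions, timing jitter, merges, splits) so the evaluation stack
can be validated against analytically known precision and recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.fft import rfft, rfftfreq

from .compare import ComparisonParams
from .mda import Firings, Recording
from .quality import FilterSpec, filter_gain

__all__ = [
    "SimulationSpec",
    "PerturbationSpec",
    "make_templates",
    "simulate_recording",
    "poisson_train",
    "perturb_sorting",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic ground-truth recording."""

    num_channels: int = 4
    num_units: int = 2
    duration_s: float = 60.0
    sample_rate: float = 30000.0
    firing_rates: Optional[Sequence[float]] = None  # Hz per unit; default 5 Hz
    target_snrs: Optional[Sequence[float]] = None  # per unit; default 8
    noise_sd: float = 10.0  # uV
    amplitude_gamma_shape: float = 20.0
    template_width_ms: float = 0.4  # main depolarization Gaussian sigma x2
    spatial_decay_um: float = 40.0
    channel_pitch_um: float = 20.0
    drift: str = "none"  # none | linear | sinusoidal
    drift_displacement_um: float = 10.0
    drift_period_s: float = 600.0
    seed: int = 0

    def __post_init__(self):
        if self.num_channels < 1 or self.num_units < 1:
            raise ValueError("need at least one channel and one unit")
        if self.duration_s <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample rate must be positive")
        if self.drift not in ("none", "linear", "sinusoidal"):
            raise ValueError(f"unknown drift model {self.drift!r}")

    @property
    def rates(self) -> np.ndarray:
        r = self.firing_rates
        if r is None:
            r = [5.0] * self.num_units
        r = np.asarray(r, dtype=float)
        if len(r) != self.num_units or np.any(r <= 0):
            raise ValueError("firing_rates must be positive, one per unit")
        return r

    @property
    def snrs(self) -> np.ndarray:
        s = self.target_snrs
        if s is None:
            s = [8.0] * self.num_units
        s = np.asarray(s, dtype=float)
        if len(s) != self.num_units:
            raise ValueError("target_snrs needs one value per unit")
        return s

    def geometry(self) -> np.ndarray:
        """Vertical probe: channels along y at the configured pitch."""
        y = self.channel_pitch_um * np.arange(self.num_channels)
        return np.column_stack([np.zeros(self.num_channels), y])


@dataclass(frozen=True)
class PerturbationSpec:
    """Controlled degradations applied to a ground-truth sorting."""

    deletion_prob: float = 0.0
    insertion_rate: float = 0.0  # Hz per unit
    jitter_sd: float = 0.0  # samples
    merge_pairs: tuple = ()  # (absorbed_label, into_label) pairs
    split_fraction: dict = field(default_factory=dict)  # label -> fraction moved
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.deletion_prob <= 1.0:
            raise ValueError("deletion_prob must lie in [0, 1]")
        if self.insertion_rate < 0 or self.jitter_sd < 0:
            raise ValueError("rates and jitter must be non-negative")
        for frac in self.split_fraction.values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("split fractions must lie in [0, 1]")


def _temporal_kernel(spec: SimulationSpec) -> np.ndarray:
    """Biphasic difference-of-Gaussians spike shape, peak amplitude -1."""
    rate = spec.sample_rate
    w_pre = round(1e-3 * rate)
    w_post = round(2e-3 * rate)
    t = (np.arange(-w_pre, w_post) / rate) * 1e3  # ms relative to event
    s1 = spec.template_width_ms / 2.0
    s2 = spec.template_width_ms
    kernel = -np.exp(-0.5 * (t / s1) ** 2) + 0.55 * np.exp(-0.5 * ((t - 0.6) / s2) ** 2)
    return kernel / np.max(np.abs(kernel))


def _spatial_profile(
    spec: SimulationSpec, source: np.ndarray, geometry: np.ndarray
) -> np.ndarray:
    dist = np.linalg.norm(geometry - source[None, :], axis=1)
    return np.exp(-dist / spec.spatial_decay_um)


def _snr_calibration(spec: SimulationSpec, filter_spec: FilterSpec) -> float:
    """Scale factor aligning raw template peak with measured (filtered) SNR.

    The SNR metric filters the trace first, which attenuates wideband noise by
    the rms filter gain and reshapes the template peak by its in-band
    transfer.  Both factors are closed-form given the filter, so the inserted
    amplitude is scaled such that filtered-peak / filtered-noise equals the
    requested SNR.
    """
    n = int(round(spec.sample_rate * 1.0))  # 1 s grid is ample for smooth gains
    freqs = rfftfreq(n, d=1.0 / spec.sample_rate)
    gain = filter_gain(freqs, filter_spec)
    # rms gain over the two-sided spectrum (rfft grid is symmetric-equivalent)
    noise_factor = float(np.sqrt(np.mean(gain**2)))
    kernel = _temporal_kernel(spec)
    padded = np.zeros(n)
    padded[: len(kernel)] = kernel
    filtered = np.fft.irfft(np.asarray(rfft(padded)) * gain, n=n)
    peak_factor = float(np.max(np.abs(filtered)) / np.max(np.abs(kernel)))
    return noise_factor / peak_factor


def make_templates(
    spec: SimulationSpec, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Units x channels x samples templates with raw peak = target_snr * noise_sd."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    sources = _unit_sources(spec, rng)
    kernel = _temporal_kernel(spec)
    geometry = spec.geometry()
    out = np.zeros((spec.num_units, spec.num_channels, len(kernel)))
    noise_ref = spec.noise_sd if spec.noise_sd > 0 else 1.0  # uV ref when noiseless
    for u in range(spec.num_units):
        amps = _spatial_profile(spec, sources[u], geometry)
        template = amps[:, None] * kernel[None, :]
        peak = np.max(np.abs(template))
        out[u] = template * (spec.snrs[u] * noise_ref / peak)
    return out


def _unit_sources(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Random source positions near the probe (x offset, y along the array)."""
    y_max = spec.channel_pitch_um * (spec.num_channels - 1)
    x = rng.uniform(5.0, 20.0, size=spec.num_units)
    y = rng.uniform(0.0, max(y_max, 1.0), size=spec.num_units)
    return np.column_stack([x, y])


def poisson_train(
    rate_hz: float,
    duration_s: float,
    sample_rate: float,
    rng: np.random.Generator,
    refractory_gap_s: float = 0.002,
) -> np.ndarray:
    """Homogeneous Poisson event times (1-based samples), thinned to enforce
    a minimum gap between consecutive events.

    Raises if thinning removes more than half of the events, which signals a
    rate incompatible with the refractory assumption.
    """
    expected = rate_hz * duration_s
    n_draw = int(expected + 5 * np.sqrt(expected) + 10)
    isis = rng.exponential(1.0 / rate_hz, size=n_draw)
    times = np.cumsum(isis)
    times = times[times < duration_s]
    kept = []
    last = -np.inf
    for t in times:
        if t - last >= refractory_gap_s:
            kept.append(t)
            last = t
    if len(times) and len(kept) < 0.5 * len(times):
        raise ValueError(
            f"rate {rate_hz} Hz incompatible with refractory gap "
            f"{refractory_gap_s * 1e3:.1f} ms: thinning removed "
            f"{len(times) - len(kept)} of {len(times)} events"
        )
    samples = np.floor(np.asarray(kept) * sample_rate).astype(np.int64) + 1
    return np.unique(samples)


def _drift_offset(spec: SimulationSpec, t_s: np.ndarray) -> np.ndarray:
    if spec.drift == "none":
        return np.zeros_like(t_s)
    if spec.drift == "linear":
        return spec.drift_displacement_um * (t_s / spec.duration_s)
    return spec.drift_displacement_um * np.sin(
        2.0 * np.pi * t_s / spec.drift_period_s
    )


def _drift_amplitudes(
    spec: SimulationSpec,
    source: np.ndarray,
    geometry: np.ndarray,
    offsets_um: np.ndarray,
) -> np.ndarray:
    """Per-event channel amplitude profiles under vertical drift.

    Amplitudes are tabulated on a 0.5 um virtual grid of vertical source
    shifts and read off by Gaussian-kernel interpolation, as done when
    drifting recordings are synthesized from a densely sampled layout.
    """
    grid_step = 0.5
    max_off = float(np.max(np.abs(offsets_um))) if len(offsets_um) else 0.0
    grid = np.arange(-max_off - grid_step, max_off + 2 * grid_step, grid_step)
    profiles = np.empty((len(grid), len(geometry)))
    for i, g in enumerate(grid):
        shifted = source + np.array([0.0, g])
        profiles[i] = _spatial_profile(spec, shifted, geometry)
    # Gaussian kernel weights over the virtual grid, sd = grid step
    w = np.exp(-0.5 * ((offsets_um[:, None] - grid[None, :]) / grid_step) ** 2)
    w /= w.sum(axis=1, keepdims=True)
    return w @ profiles


def simulate_recording(
    spec: SimulationSpec, filter_spec: FilterSpec = FilterSpec()
) -> tuple[Recording, Firings]:
    """Generate a ground-truth recording and its true firings.

    Deterministic given the spec (the seed fixes all randomness).  Inserted
    amplitudes are calibrated so that the measured, filtered-trace SNR of each
    unit approximates its ``target_snr``.
    """
    rng = np.random.default_rng(spec.seed)
    num_samples = int(round(spec.duration_s * spec.sample_rate))
    geometry = spec.geometry()
    sources = _unit_sources(spec, rng)
    kernel = _temporal_kernel(spec)
    w_pre = round(1e-3 * spec.sample_rate)
    calib = _snr_calibration(spec, filter_spec)

    traces = (
        rng.normal(0.0, spec.noise_sd, size=(spec.num_channels, num_samples))
        if spec.noise_sd > 0
        else np.zeros((spec.num_channels, num_samples))
    )

    all_channels, all_times, all_labels = [], [], []
    delta = ComparisonParams(sample_rate=spec.sample_rate).delta_samples
    refractory_gap_s = 2.0 * delta / spec.sample_rate
    for u in range(spec.num_units):
        times = poisson_train(
            spec.rates[u], spec.duration_s, spec.sample_rate, rng, refractory_gap_s
        )
        # keep events whose clip lies fully inside the recording
        times = times[(times - 1 - w_pre >= 0) & (times - 1 + len(kernel) - w_pre <= num_samples)]
        scales = rng.gamma(
            spec.amplitude_gamma_shape, 1.0 / spec.amplitude_gamma_shape, size=len(times)
        )
        t_s = (times - 1) / spec.sample_rate
        offsets = _drift_offset(spec, t_s)
        if spec.drift == "none" or spec.drift_displacement_um == 0.0:
            amps = np.tile(
                _spatial_profile(spec, sources[u], geometry), (len(times), 1)
            )
        else:
            amps = _drift_amplitudes(spec, sources[u], geometry, offsets)
        base_peak = np.max(np.abs(kernel)) * np.max(
            _spatial_profile(spec, sources[u], geometry)
        )
        noise_ref = spec.noise_sd if spec.noise_sd > 0 else 1.0  # uV ref when noiseless
        gain = spec.snrs[u] * noise_ref * calib / base_peak
        peak_channel = int(np.argmax(_spatial_profile(spec, sources[u], geometry)))
        for i, t in enumerate(times):
            start = int(t) - 1 - w_pre
            waveform = gain * scales[i] * amps[i][:, None] * kernel[None, :]
            traces[:, start : start + len(kernel)] += waveform
        all_channels.append(np.full(len(times), peak_channel + 1, dtype=float))
        all_times.append(times.astype(float))
        all_labels.append(np.full(len(times), u + 1, dtype=np.int64))

    order = np.argsort(np.concatenate(all_times), kind="stable")
    firings = Firings(
        channels=np.concatenate(all_channels)[order],
        times=np.concatenate(all_times)[order],
        labels=np.concatenate(all_labels)[order],
    )
    recording = Recording(
        traces.astype(np.float32), spec.sample_rate, geometry
    )
    return recording, firings


def perturb_sorting(
    gt: Firings,
    pspec: PerturbationSpec,
    duration_samples: Optional[int] = None,
    sample_rate: float = 30000.0,
) -> tuple[Firings, dict]:
    """Degrade a ground-truth sorting with known expected metrics.

    Order of operations: deletions, jitter, insertions, merges, splits.
    Returns the pseudo-sorting and a record of analytic expectations:
    ``expected_recall`` is about 1 - deletion_prob (valid for jitter well
    below the matching tolerance) and ``expected_precision`` is
    kept / (kept + inserted), both per unit.
    """
    rng = np.random.default_rng(pspec.seed)
    if duration_samples is None:
        duration_samples = int(np.max(gt.times)) if len(gt) else 0
    channels = gt.channels.copy()
    times = gt.times.copy()
    labels = gt.labels.copy()

    keep = rng.random(len(times)) >= pspec.deletion_prob
    channels, times, labels = channels[keep], times[keep], labels[keep]

    if pspec.jitter_sd > 0:
        times = times + np.round(rng.normal(0.0, pspec.jitter_sd, size=len(times)))
        times = np.clip(times, 1, max(duration_samples, 1))

    expectations: dict = {"per_unit": {}}
    ins_counts: dict[int, int] = {}
    if pspec.insertion_rate > 0 and duration_samples > 0:
        duration_s = duration_samples / sample_rate
        for label in np.unique(gt.labels):
            n_ins = rng.poisson(pspec.insertion_rate * duration_s)
            ins_counts[int(label)] = n_ins
            if n_ins == 0:
                continue
            ins_t = np.floor(rng.uniform(1, duration_samples + 1, size=n_ins))
            times = np.concatenate([times, ins_t])
            labels = np.concatenate([labels, np.full(n_ins, label, dtype=np.int64)])
            channels = np.concatenate([channels, np.zeros(n_ins)])

    for absorbed, into in pspec.merge_pairs:
        labels = np.where(labels == absorbed, into, labels)

    next_label = int(labels.max()) + 1 if len(labels) else 1
    for label, frac in pspec.split_fraction.items():
        idx = np.flatnonzero(labels == label)
        moved = idx[rng.random(len(idx)) < frac]
        labels[moved] = next_label
        next_label += 1

    for label in np.unique(gt.labels):
        n_gt = int(np.count_nonzero(gt.labels == label))
        n_kept = int(np.count_nonzero((gt.labels == label) & keep))
        n_ins = ins_counts.get(int(label), 0)
        expectations["per_unit"][int(label)] = {
            "expected_recall": 1.0 - pspec.deletion_prob,
            "expected_precision": (
                n_kept / (n_kept + n_ins) if n_kept + n_ins else 0.0
            ),
            "n_gt": n_gt,
            "n_kept": n_kept,
            "n_inserted": n_ins,
        }

    order = np.argsort(times, kind="stable")
    perturbed = Firings(channels[order], times[order], labels[order])
    return perturbed, expectations
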