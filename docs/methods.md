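# Methods

## Event matching and per-unit scores

Matching uses an absolute timing tolerance Δ, default 1 ms, converted to
samples as `delta_samples = round(delta_ms · rate / 1000)` (minimum 1) and
compared inclusively (|t − s| ≤ Δ). The match count for a (ground-truth unit
l, sorted unit k) pair is the number of ground-truth events with *at least
one* sorted event of k inside the window — an existence count, so a burst of
several sorted events near one true event contributes a single match, and the
surplus surfaces as false positives through `n_fp = M_k − n_match`. The
implementation uses a binary search per ground-truth event
(O((N+M) log M)); the test suite checks exact agreement with a literal
O(N·M) evaluation on hundreds of random instances.

The matching logic assumes Δ is below half the refractory period of any true
neuron, which guarantees a sorted event cannot sit within Δ of two
ground-truth events of the same unit. The assumption is not enforced — a
warning is logged when any within-unit gap is below 2Δ, and the formulas are
applied literally regardless.

Each ground-truth unit is assigned the sorted unit with the highest pair
accuracy; ties break to the smallest sorted label so results are
deterministic. When the best accuracy is 0 the unit is reported unmatched
with all metrics 0. Several ground-truth units may share one best-matching
sorted unit; this is reported via logging but allowed. Event times are
floored to integer samples before windowed comparisons; fractional times in
firings files are accepted.

Per-event categorization (for waveform galleries: matched / missed /
false-positive) assigns matched sorted events greedily — each matched
ground-truth event claims its nearest unclaimed sorted event — which makes
the category counts agree with the match count on both sides whenever the
refractory assumption holds.

## SNR

The SNR filter multiplies each channel's full-length FFT by

    A(f) = 1/2 · sqrt(1 + erf((|f| − fmin)/w_lo)) · sqrt(1 − erf((|f| − fmax)/w_hi))

with fmin = 300 Hz, fmax = 6000 Hz, w_lo = 100 Hz, w_hi = 1000 Hz. The square
roots on each factor make the passband gain exactly 1 (without them it would
be 2); the gain is real and even in f, so the filter is zero-phase and the
output real. No windowing or overlap is used: desk-scale recordings fit in
memory and a single FFT per channel is both exact and simple. Note the
1000 Hz upper roll-off is wide enough that the gain is already ~0.1 % below 1
at 4 kHz; "flat passband" statements should be read on roughly 1–3.6 kHz.

Noise is estimated per channel as MAD/0.6745, the robust Gaussian-SD
estimator, on the filtered trace of the channel where the average waveform
peaks. The average waveform uses a 1 ms pre / 2 ms post clip window around
each (floored) event time — wide enough for typical spike widths; events
whose clip crosses a recording boundary are dropped. SNR = peak |average
waveform| / noise; a zero noise estimate yields an explicit infinity rather
than an error. SNR is invariant under positive rescaling of the recording.

## ISI-violation ratio

With N events in duration T and refractory threshold t_ref = 2.5 ms, the
ratio is V / E where V counts inter-spike intervals below t_ref and

    E = (N − 1) · (1 − exp(−λ t_ref)),   λ = N / T,

the expected number of sub-threshold intervals for a homogeneous Poisson
train of the same rate: each of its N − 1 intervals is exponential(λ). By
construction the ratio calibrates to ≈ 1 on Poisson trains (verified at 1, 5
and 20 Hz) and to 0 on any train with all gaps above t_ref. Other
expected-count conventions (e.g. pairwise-rate formulas) differ by a constant
factor; this one was chosen because it makes the Poisson reference exactly
interpretable. Fewer than two events yields NaN.

## Aggregation and imputation

Per study, the average of a per-unit metric is the *unweighted* mean over
ground-truth units — units are treated equally, not weighted by event count —
restricted to units with SNR at or above the threshold (default 8). The
study-set value is the unweighted mean of its study means (the roll-up
granularity was an open choice; mean-of-means keeps small studies from being
swamped).

When a sorting run failed or timed out, its (sorter, recording) cell is
masked. For averages, per-recording mean accuracies are imputed: one OLS
model per (sorter, study set), fit with intercept of the sorter's observed
per-recording means on the means of all sorters with no missing data at the
same recordings, then evaluated at the missing recordings and clipped to
[0, 1]. If no complete sorter exists, or the sorter has fewer observations
than predictors + 1, the fallback is the sorter's own observed mean; with no
observations the cell stays missing. An imputed recording enters its study
average weighted by the recording's number of qualifying ground-truth units
(known from the sorters that succeeded), which preserves the equal-unit
weighting of the observed data. Counts of units above the accuracy threshold
(default 0.8) are never imputed — missing recordings contribute zero and the
cell is flagged — because fabricating a count would misrepresent what was
actually found.

The accuracy predictor regresses per-unit accuracy on SNR, firing rate, and
log ISI-vr (natural log; zeros floored at half the smallest positive observed
value) with an intercept, via OLS, and reports the Pearson correlation
between predicted and observed accuracy. Exactly collinear predictors are
dropped, not pseudo-inverted, and the dropped names are returned.

## Synthetic generator

The generator emulates phenomenological template-insertion simulations:

* **Templates.** A biphasic difference-of-Gaussians temporal kernel (main
  width 0.4 ms, opposite-sign rebound at +0.6 ms) on a 1 ms pre / 2 ms post
  support, times a per-channel amplitude decaying exponentially
  (length constant 40 µm) with distance from a random source placed near the
  probe (vertical channel layout, 20 µm pitch). `make_templates` normalizes
  the raw peak to `target_snr × noise_sd`.
* **Firing.** Per unit, homogeneous Poisson times thinned to enforce a
  minimum gap of 2Δ (2 ms at defaults), honoring the matching assumption; a
  rate whose thinning removes over half the events is rejected as
  inconsistent. Defaults: 5 Hz per unit.
* **Amplitude jitter.** Each event's template is scaled by a Gamma(k, 1/k)
  draw, mean 1; default shape k = 20 gives ~22 % amplitude CV — the
  distribution family is standard for this style of simulator, the shape is
  this package's documented default.
* **Noise.** iid Gaussian per sample and channel, default 10 µV SD.
  Spectrum-matched or spatially correlated noise is out of scope, so measured
  noise floors are slightly idealized relative to real recordings.
* **SNR calibration.** Measured SNR is defined on the *filtered* trace, which
  attenuates white noise by the rms filter gain (≈ 0.63 at a 30 kHz rate) and
  the template peak by its in-band transfer (≈ 0.97 for the default kernel).
  Inserted amplitudes are therefore scaled by the closed-form ratio of the
  two factors, computed from the filter spec at run time, so that
  `compute_snr` recovers `target_snr` (verified within 10 % for targets
  5–12). With `noise_sd = 0` the SNR reference is degenerate; templates then
  use a 1 µV reference so the noiseless recording is still a faithful sum of
  scaled templates.
* **Drift.** Optional linear or sinusoidal vertical motion of each unit's
  source (defaults ±10 µm, 600 s period). Per-event channel amplitudes are
  read from a table of spatial profiles computed on a 0.5 µm virtual grid of
  vertical shifts, blended with a Gaussian kernel (SD = grid step) — the
  dense-grid interpolation scheme used when drifting recordings are
  synthesized by shifting electrode positions. Zero displacement reproduces
  the static simulation bit-for-bit. The temporal kernel itself does not
  change with drift; only the spatial amplitude profile moves.

All randomness flows from a single integer seed through one
`numpy.random.Generator`; identical specs give bit-identical recordings.

`perturb_sorting` applies, in order: independent per-event deletions,
Gaussian timing jitter (rounded to samples), uniform spurious insertions
(Poisson count at the configured rate per unit), merges (relabeling), and
splits (reassigning a random fraction of a unit to a fresh label). It returns
the realized per-unit expectations — recall ≈ 1 − deletion_prob for jitter ≪
Δ, precision = kept/(kept + inserted) — so tests can compare measured metrics
against analytic values with binomial error bars.

## What the synthetic tests do and do not show

Passing the recovery tests shows the evaluation machinery is correct:
matching, metric algebra, filtering, noise estimation and aggregation behave
exactly as specified on data whose ground truth is known by construction.
It does not show that any real sorter achieves any particular accuracy, nor
does the generator reproduce real-data difficulties — overlapping spikes from
correlated units, bursting with amplitude decrement, correlated or
non-stationary noise, electrode-specific artifacts. Conclusions about real
recordings require real or biophysically simulated ground truth.

## Problem sizes

Default test and validation runs use desk-scale problems: up to 8 channels,
5 units, 300 s at 30 kHz for the identity check; 120 s recordings for SNR
recovery; 2 500 events per unit for perturbation recovery; hour-long spike
trains (times only, no traces) for ISI calibration. These sizes keep the full
suite under a minute of compute while leaving Monte-Carlo error well inside
the asserted tolerances.
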