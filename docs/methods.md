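# Methods

## The pulse model and its closed forms

The depolarization waveform is phenomenological, not biophysical: a
trapezoid with sag. From onset, the pulse rises linearly to amplitude `A`
(ΔF/F) over the rise time `r` (s), sags linearly from `A` to `p·A` over the
plateau duration `d` (s) with plateau-end fraction `p ∈ (0, 1]`, and falls
linearly back to baseline over the fall time `f` (s). An optional Gaussian
convolution (`σ_shape`, s) rounds the corners; with `σ_shape = 0` the five
waveform metrics have closed forms used throughout as the oracle for the
extractor:

- `h_max = A`; upslope crossing `t_up = r/2`; `m_up = A/r`;
- for `p ≥ 1/2` the half-maximum falls on the fall limb:
  `t_down = r + d + f(p − ½)/p`, `m_down = −pA/f`;
  for `p < 1/2` (requires `d > 0`) it falls on the sag:
  `t_down = r + d/(2(1 − p))`, `m_down = −(1 − p)A/d`;
- `w = t_down − t_up`; `h_plateau` is the pulse value at `(t_up + t_down)/2`.

`p < 1/2` with `d = 0` leaves the falling-limb half-maximum crossing
undefined and is rejected as a degenerate pulse.

## Synthetic study conditions

Three conditions emulate β-adrenergic pharmacology. Condition means
(`A`, `r`, `d`, `f`, `p`; beat rate in beats/min):

| condition     | A     | r     | d    | f    | p    | rate |
|---------------|-------|-------|------|------|------|------|
| control       | 0.200 | 0.100 | 0.18 | 0.25 | 0.75 | 70   |
| propranolol   | 0.190 | 0.105 | 0.30 | 0.31 | 0.74 | 52   |
| isoproterenol | 0.260 | 0.080 | 0.13 | 0.20 | 0.82 | 92   |

Per-parameter standard deviations (shared by all conditions) are
A 0.028, r 0.030, d 0.038, f 0.080, p 0.040. Variance splits
hierarchically: a fraction 0.10 sits at the cell (recording) level as a
mean shift shared by all beats of a recording, the rest is beat-to-beat
jitter. Draws violating positivity or `p ∈ (0.55, 0.98]` are redrawn
(truncation), keeping every generated pulse non-degenerate. Inter-beat
intervals are Gaussian-jittered at 5% sd around the condition rate.

Only the *directions* of these effects are grounded in the pharmacology
(isoproterenol: positive chronotropy, taller/faster/narrower waveform with
a higher plateau; propranolol: negative chronotropy, wider waveform); the
magnitudes are calibration constants committed once. They were chosen so
that (a) no single metric separates the classes, (b) the reduced 3-feature
forest's held-out per-waveform accuracy, per-condition mean true-class
vote score (> 60%) and wrong-class vote scores (< 30%) land in the regime
the method reports, robustly across seeds. The rise- and fall-time
variability is deliberately large so that the two slope metrics carry the
least class information — matching the expectation that β-adrenergic drugs
act on plateau-phase calcium transport, not the fast sodium/potassium
currents that set the slopes. Under this calibration held-out accuracy sits
at 80–89% depending on seed, at the top of (and slightly above) the 65–80%
band originally targeted: pushing accuracy lower by widening the overlap
collapses the control condition's true-class vote score below 60%, because
control is squeezed between both drug classes. The vote-score bounds took
priority.

The default feature table holds 457 waveforms (145/100/212), i.e. class
proportions 32/22/46%, spread over 4 recordings per condition.

## Recording synthesis

A recording is `n_lines × 128` pixels, one line per `line_period` (default
2 ms; duration is deliberately a free parameter). Each membrane is a
Gaussian profile (σ_psf = 2 px) whose amplitude is
`bleach(t)·(1 + V_m(t))` with `V_m` the membrane's pulse train and
`bleach(t) = a·e^{bt} + c·e^{dt}` (defaults 800, −0.02 s⁻¹, 200,
−0.002 s⁻¹). All membranes of a cluster share beat onsets and a common
beat-coupled displacement: membrane 1's pulse train passed through a
single-pole low-pass (τ = 0.15 s) and scaled to the configured pixel
amplitude (default 1.5 px). Noise is additive Gaussian (sd relative to the
initial bleach level, default 0.005) or Poisson counting noise. Membranes
closer than 4σ_psf trigger an "unresolvable" warning; motion that pushes a
centre out of frame is an error. Everything is reproducible bit-for-bit
from the seed.

What the generator does **not** emulate: arrhythmic beats, waveform shapes
beyond the trapezoid family, focus drift, non-Gaussian membrane profiles,
spatially varying background, or correlated (1/f) noise. Passing tests
therefore demonstrate the pipeline's correctness and its statistical
behaviour under the modelled regime, not robustness to every artifact of
real microscopy.

## Tracking

Membrane candidates are local maxima of the time-averaged profile with
prominence above max(20% of the profile range, 5× the profile's
successive-difference MAD noise scale), ≥ 4 px apart, refined to sub-pixel
by parabolic interpolation. Tracking is causal: each line's
Gaussian-plus-offset fit is seeded at the previous accepted centre and
restricted to ± 6 px (configurable). A line is flagged when the fit fails,
the centre jumps beyond the search half-width, or the fitted amplitude is
insignificant (below 3× the fit residual RMS, or below 5% of the first
accepted amplitude); flagged lines are filled by linear interpolation, and
more than 20% flagged lines abort with a "tracking unreliable" error. The
corrected intensity is the fitted amplitude — width-invariant and
background-free — rather than a windowed sum.

## Bleach correction and smoothing

The two-exponential model is fitted to the full trace, beats included; the
bias this induces is bounded by the beat duty cycle and verified to keep the
beat-free baseline of ΔF/F within ±0.02. Seeding is two-timescale: a
log-linear fit on the last third gives the slow component, a log-linear fit
of the early residual gives the fast one; rates are bounded ≤ 0 and
amplitudes ≥ 0. On failure the fitter falls back to a single exponential,
then to the trace mean, recording the fallback. Normalization is
division by the time-varying fit (ΔF/F), not by a scalar baseline.

Smoothing is a centred moving average, default 50 lines regardless of line
period (the window is configurable). Even windows keep their stated width
with the extra sample placed before the centre, so the impulse response is
exactly a `1/window` boxcar; edges shrink the window rather than inventing
padding. `smooth` also records the pre-smoothing noise sd (1.4826 × MAD of
the residual about a running median shorter than a beat) in the trace
metadata: this raw-noise scale is the reference for beat detection, since
beats survive smoothing while noise does not.

## Beat segmentation and metrics

Peaks require prominence ≥ 4× the recorded raw noise sd (floored at a tiny
relative value so noiseless traces work) and ≥ 0.2 s separation. Troughs
are the minima between consecutive peaks, with the trace ends bounding the
outer segments. Beat rate is 60 / median inter-peak interval, reported as 0
with fewer than two beats. Per beat, the baseline is the mean of the two
flanking trough values; half-maximum crossings are linearly interpolated,
taking the crossing nearest the peak on each limb; slopes are central
differences at the bracketing samples interpolated to the crossing time.
Beats without a crossing on either limb (non-monotone pathologies) are
rejected with a reason and counted in the QC report, never silently
dropped.

## Classifier

Trees are CART (Gini, unlimited depth, minimum leaf 1, `⌈√p⌉` features per
split — 3 of 5, 2 of 3), each grown on a bootstrap resample the size of the
training set. The OOB error curve evaluates, cumulatively at 1..n_trees,
the majority vote of the trees for which each training row is out-of-bag;
50 trees sit on the curve's plateau. Importance is standardized OOB
permutation importance: the across-tree mean increase in a tree's OOB error
after permuting a feature, divided by its across-tree standard deviation —
the "< 1" removal threshold is therefore a signal-to-noise cut. Prediction
scores are vote fractions; class calls are the argmax (ties to the first
class in sorted order). Reduction removes all features below the threshold
at once, then single weakest features, retraining each time, and stops when
held-out accuracy drops by more than 5 percentage points (configurable) or
2 features remain. Recording-level calls are the mode of per-waveform
calls, ties broken by the higher within-recording mean vote score.

One behaviour worth noting: under label permutation the OOB accuracy of
deep bagged trees settles near the "match-the-neighbour" rate (≈ Σ p_c²,
here ≈ 36–41%) rather than at the majority-class rate (46%), because leaves
of size 1 reproduce the label of a row's nearest bootstrap neighbour and
those votes are correlated across trees. scikit-learn's
`RandomForestClassifier(oob_score=True)` shows the same behaviour, even
with 1000 trees. The chance-level control in the test suite asserts this
band; it is the correct null for this classifier family.

## Evaluation

ROC curves are one-vs-rest per class, sweeping the observed vote-fraction
values (tied scores collapse to one threshold step); AUC is trapezoidal.
Group statistics are pairwise pooled-variance Student's t-tests per metric
(Welch by flag), one-way ANOVA and Tukey HSD across the three conditions,
all at α = 0.05; no multiple-testing correction is applied beyond Tukey,
and every report states its own denominators.

## Problem sizes

Default test and acceptance sizes: the 457-waveform table for all
classifier work; recordings of 4,000–10,000 lines (8–20 s) for
image-pipeline tests; 1,000 recordings × 60 waveforms for the aggregation
simulation; 50 trees everywhere (500 only to confirm curve stability).
These sizes give Monte-Carlo error well inside every asserted tolerance.

## Known limitations

- The tracker is 1-D and causal; it cannot recover a membrane that leaves
  the search window for many consecutive lines (by design, this aborts).
- The bleach fit is biased upward by high-duty-cycle beating; trough-masked
  fitting is not implemented.
- The aggregation simulation draws waveform calls independently; real
  recordings share cell-level effects, so its 100% figure bounds the
  independent-call regime only.
- Metrics assume a single dominant peak per beat; alternans or fused beats
  are rejected by QC rather than modelled.
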