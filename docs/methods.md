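# Methods

## Problem and scope

Wearable accelerometry studies summarise raw triaxial acceleration with a
variety of movement-intensity metrics (MAI, ENMO, MAD, ActiGraph-style
counts/CPM) recorded at a variety of body positions (thigh, hip, chest,
ankle, wrist, upper arm). The numbers these pipelines produce are not
directly comparable: means differ across metrics and positions, and the
relations between activities change with both. `accelharm` implements the
metric definitions, the comparability workflow (descriptives,
between-person variance, the 24 x 24 Pearson correlation matrix over
(metric, location) series, pairwise linear conversion models, intensity
cut-points), a packaged copy of published reference tables for those
quantities, and a synthetic cohort generator so the entire workflow runs
and is testable fully offline.

## Metric definitions

All metrics aggregate over half-open one-second epochs
`[k, k+1)` anchored at the signal start (trailing partial epochs dropped);
values are computed in g and converted to mg exactly once, at epoch
aggregation. Input signals are uniformly sampled at a nominal 64 Hz within
a +/- 16 g range.

* **MAI** — each axis is band-pass filtered with a Butterworth design of
  order 4, corners 0.25–11 Hz; the per-sample Euclidean norm of the
  filtered axes is averaged per epoch. The filter is applied causally by
  default (streaming-compatible, like commercial firmware); a zero-phase
  forward–backward mode is available via `FilterSpec.phase`. Whether
  "order 4" means the design order of the band-pass prototype or of each
  section is genuinely ambiguous in the field; we pass 4 as the design
  order to `scipy.signal.butter`, and the choice is a config knob.
* **ENMO** — `max(||a|| - 1, 0)` per sample, averaged per epoch. The
  clipping rule makes the metric exactly zero for any static posture.
* **MAD** — per epoch, `mean(| ||a_i|| - mean(||a||) |)`. Removes gravity
  by subtraction of the epoch mean instead of filtering; exactly zero for
  constant-magnitude signals.
* **Counts/CPM** — per axis: polyphase resampling from 64 Hz to 30 Hz,
  Butterworth band-pass 0.29–1.63 Hz (order 4, causal), clipping to
  +/- 2.13 g, rectification, an analog deadband at 0.068 g, quantization to
  12-bit ADC levels, and one count per level beyond 128, summed per
  one-second epoch. Axis counts are combined by Euclidean norm. CPM is the
  per-second counts x 60 for second-level analyses (a constant rescaling
  that leaves Pearson correlations unchanged) and mean-over-condition x 60
  for descriptives; the two coincide because the mean commutes with the
  scaling.

### Count-algorithm numerical choices

The ADC resolution is `peak_g / 2**adc_bits` = 0.00052 g per level, which
makes the level threshold (128 levels = 0.0666 g) consistent with the
analog deadband (0.068 g); both stages are kept, the level threshold being
the binding one. Per-sample counts are
`max(floor(|x| / resolution) - 128, 0)`. These constants are a documented
dialect: different device generations and open-source reimplementations
differ in filter coefficients and in the deadband/quantization interplay,
so every constant is overridable via `CountConfig`. No quantitative
equivalence to any specific device's output is claimed; the invariants
that matter downstream (non-negativity, integer per-axis epoch counts,
zero counts for static postures, monotone response to in-band amplitude)
hold for the whole config family.

### Filter-edge handling

No padding or initial-condition correction is applied to the causal
filters. The first and last five seconds of every condition are discarded
by the pipeline anyway, which removes most of the start transient; the
0.25 Hz corner of the MAI filter rings down below 1 mg only after roughly
15 s, so steady-state assertions in the tests skip the first 15 epochs.

## Statistical workflow

Given a long cohort table (participant, location, condition, category,
metric, second, value):

* **Trimming** removes the first and last 5 s of every condition (start
  and stop behaviour is not the activity). **Truncation** then cuts every
  stream of a condition — all participants, locations, metrics — to the
  common minimum length, keeping the earliest seconds, so all series stay
  aligned on (participant, condition, second). Misalignment downstream is
  a hard error, never silent dropping.
* **Categories**: conditions are grouped into eight superordinate
  categories (lying, sitting, standing, adl, climbing_stairs, walking,
  jogging, cycling) via an editable YAML mapping (a 32-entry default
  ships with the package); an unmapped condition is a configuration
  error naming the offender.
* **Descriptives**: mean and SD per (location, category, metric). SDs use
  the sample (n-1) denominator throughout. By default seconds are pooled
  across participants (the same resolution as the correlation analysis);
  a participant-means variant is available because both pooling
  conventions are defensible and they give different numbers.
* **Between-person variance**: participant means first, then the SD
  across participants per cell; plus the mean of those SDs per
  (location, metric) for position-level comparison. Single-participant
  cells yield an undefined SD and a warning.
* **Correlations**: Pearson r over pooled seconds for all pairs of the
  24 (metric, location) series — 276 unique pairs. Zero-variance series
  produce missing (NaN) correlations with a warning, never 0.
* **Conversion models**: OLS `target = slope * source + intercept` per
  series pair (via `scipy.stats.linregress`), reporting slope, intercept,
  their standard errors, r, r^2 and n. The model's r equals the
  correlation-matrix entry by construction; tests pin this to 1e-12.
* **Cut-points**: for an ordered ladder of intensity classes (default:
  sedentary = lying+sitting, light = standing+adl, moderate =
  walking+stairs+cycling, vigorous = jogging), each boundary threshold
  maximizes Youden's J in a one-vs-rest ROC over pooled seconds
  (`sklearn.metrics.roc_curve`); the reported threshold is the midpoint
  between the boundary value and the next distinct value below it, so it
  lies strictly between classes when they separate. Boundaries with
  J < 0.5 are flagged unreliable. This ROC/Youden procedure is the
  field-standard calibration and is labelled an approximation: it is one
  of several defensible calibration criteria, and strict monotonicity of
  successive thresholds is checked and warned about rather than forced.

## Reference tables

The packaged resources hold the published descriptive table (192
mean/SD cells: 6 locations x 8 categories x 4 metrics; MAI/ENMO/MAD in
mg, CPM in counts per minute) and the published 24 x 24 correlation
matrix, stored at the printed two-decimal precision, mirrored from the
lower triangle with a unit diagonal. Summary operations (within-metric
between-location mean r, extreme pairs, activity ratios) recompute the
headline comparability numbers from these resources at run time;
presentation rounding is decimal half-up at the printed precision. When
several pairs tie at the stored precision the extreme-pair query returns
all of them — at two decimals the between-metric maximum (0.98) is a
five-way tie, and the stored between-metric minimum is 0.81
(ENMO–CPM at the chest), with the chest MAD–CPM coefficient of 0.83
available as a direct lookup.

## Synthetic cohort generator

Each stream is a posture plus periodic-movement model:

```
a(t) = g_hat + m * sum_k w_k A sin(2 pi k f t + phi_k) * u_hat + e(t)
```

with `g_hat` the unit gravity orientation (posture- and
location-dependent), `A` the location-dependent movement amplitude (mg),
`f` the activity fundamental with harmonic weights `w = {1: 1.0, 2: 0.4}`,
`u_hat` the movement axis (defaults to the gravity axis), `e` white
Gaussian noise per axis, and `m` a lognormal (median 1) amplitude
multiplier per (participant, category) carrying all between-person
variability. Default profiles span 12 conditions over the eight
categories at 2–5 min each, for a 20-participant, six-location cohort;
amplitudes are ordered so that lying <= sitting < standing < walking <
jogging at every location, wrist dominates thigh for ADL-type tasks,
legs dominate wrist for cycling, and jogging has the largest
between-person sigma (0.25) against 0.05 for recumbent postures — the
qualitative placement and variance structure of real multi-position
recordings. Phases and noise come from substreams keyed by (condition,
location), shared across participants, so zero between-person sigma
yields bit-identical participants; multipliers come from substreams
keyed by (participant, category). Everything is reproducible from a
single integer seed.

What the generator does **not** emulate: biomechanically realistic gait
(impact transients, asymmetry), sensor drift or temperature effects,
non-wear, postural transitions inside a condition, or the quantitative
magnitudes of any published table. Pipeline tests on synthetic cohorts
therefore demonstrate correctness of the computations and the directional
structure of the comparisons (orderings, variance ratios, saturation
effects), not numeric agreement with laboratory data.

## Problem sizes and tolerances

The test suite and the acceptance script run a reduced cohort — 4–6
participants with condition durations scaled to one quarter (floor 30 s,
so trimming always survives) — which preserves the profile structure the
directional checks rely on. Closed-form sinusoid limits (ENMO ->
1000·A/pi, MAD -> 2000·A/pi) are asserted within 0.5 % at 64 Hz
(discretisation of the half-sine mean); loop-oracle equivalence at 1e-9
relative, exact for counts; OLS/Pearson against the normal equations at
1e-9; rotation invariance of ENMO/MAD at 1e-12 relative with a 1e-9 mg
absolute floor; parameter recovery within 3 standard errors at n = 1000.

## Known limitations

* The count constants reproduce a family of count dialects, not any one
  device byte-for-byte.
* Cut-point calibration criteria vary across studies; only ROC/Youden is
  implemented.
* Linear conversion models are fitted pooled across activities; the
  reference correlations show that for count-type metrics the relation is
  activity-dependent and saturating, so pooled linear conversions are
  systematically less accurate there — the package quantifies this (lower
  r) but does not model it nonlinearly.
* No mixed-effects/ICC or Bland–Altman agreement analysis, and no
  device-binary ingestion; CSV is the sole interchange format.
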