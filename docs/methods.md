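# Methods

## Setting and signal model

Intrarenal pressure (IRP) is sampled at 4 Hz by a sensor at the tip of a
flexible ureteroscope. Two processes are superimposed in the recording:

- the **true pressure**: a baseline of a few mmHg to ~15 mmHg, slow drift,
  a small respiratory oscillation near 0.25 Hz, and irrigation episodes —
  minutes-scale elevations up to ~50–100 mmHg driven by irrigation inflow
  against outflow resistance;
- **contact-spike artifacts**: transient excursions caused by the tip
  sensor touching tissue, debris or stone fragments. They rise within one
  or two samples, hold a noisy plateau, and fall as quickly; amplitudes
  reach hundreds of mmHg.

The package's task is per-sample binary segmentation (artifact vs true
signal), followed by removal and exposure reporting. The positive class is
*artifact* throughout; a false negative leaves a spurious spike in the
corrected record, which is most harmful when it occurs above the 30 mmHg
safety threshold — hence the asymmetric treatment of high-pressure samples
in oversampling, post-processing and evaluation.

## Synthetic cohort simulator (`simulate`)

Clinical recordings from these devices are not publicly available, so the
package ships a seeded generator whose *cohort summary statistics* are
calibrated to published clinical aggregates for a 27-case cohort. The
clean signal is the sum, clipped at zero, of:

| component | model | defaults |
|---|---|---|
| baseline | per-case constant ~ Normal(10, 3) mmHg | |
| drift | Ornstein–Uhlenbeck, relaxation 300 s, stationary sd 2 mmHg | exact discretization |
| respiration | sinusoid at 0.25 Hz | amplitude ~ U[0.5, 2] mmHg |
| irrigation episodes | Poisson arrivals 12/h; amplitude ~ case_scale × Gamma(2, 12.5) with case_scale ~ lognormal(0, 0.4); exponential rise τ=3 s, plateau ~ U[5, 60] s, decay τ=5 s | |
| sensor noise | white Gaussian, sd 0.5 mmHg | |

Artifacts are **additive** on the clean signal (a contact spike rides on
the true pressure; corrected traces should continue smoothly through the
artifact window). Per case, the artifact count is negative-binomial
(size 3.5) with mean 135 scaled by (duration/median-duration)^0.7 — counts
accrue with operative time, damped so cohort medians stay stable; each
artifact has a lognormal duration (median 1.8 s, σ=0.7), a lognormal peak
amplitude (median 28 mmHg, σ=0.75), a 1–2-sample rise and fall, and a
plateau jittered with a per-artifact sd ~ U[10, 30] mmHg. A fraction
(0.55) of artifacts is placed inside irrigation episodes, concentrating
artifact burden at high pressure as observed clinically. Overlapping
artifacts are unioned (per-sample maximum of excursions). The truth mask
marks exactly the samples whose added excursion is non-zero, so
`trace != clean ⇔ mask == 1` holds sample-for-sample.

Calibration targets are cohort *medians* inside published interquartile
ranges: artifact spikes/case in [60, 166], artifact seconds/case in
[163, 566], raw maximum IRP in [208, 300] mmHg, artifact-free maximum in
[50, 113] mmHg, with artifact density around 6% of samples. Parameters
were fixed by moment matching plus numeric iteration over well-separated
cohort seeds and then locked. The generator matches aggregates only: it
does not model pyelovenous backflow, device hydraulics, surgeon behavior,
or inter-rater labeling noise — so passing benchmarks here demonstrates
the pipeline's mechanics, not clinical performance. Real recordings could
contain artifact morphologies (slow drifts from sensor occlusion, partial
contacts) the generator never produces.

Per-case seeds are `seed + case_index`; a fixed config is byte-identical
across runs. Note that cohorts at nearby seeds share case streams — use
well-separated seeds for independent cohorts.

## Feature set (`features`)

32 per-sample features, all computed over **trailing** windows
(left-padded by repeating the first sample), so truncating a trace never
changes earlier rows. Seven carry the names used for this task in the
clinical literature (FFT dominant frequency; peak count in the last 120
points; absolute pressure; edge position of the window-10 maximum;
duration above 30 mmHg; maximum absolute curvature over 10 points; peak
area over 10 points). The remaining 25 are this package's instantiation of
the four standard categories (derivatives, peak shape, short-term energy,
frequency); the schema is versioned so alternative sets can be swapped in.

Choices worth noting:

- **FFT window 64 samples** (16 s): the shortest power of two that
  resolves the 0.25 Hz respiratory band at 4 Hz. Dominant frequency uses
  the max-power non-DC bin of the mean-removed window, with a tolerant
  tie-break (lowest bin within 1e-9 relative of the max) because
  near-delta windows have an almost flat spectrum.
- **Peak counting** uses strict local maxima with prominence ≥ 2 mmHg
  (above sensor-noise scale), prominence computed within the window.
- **Peak area** integrates excess over a trailing-120-sample running
  median baseline, clipped at zero — a plain rolling sum would duplicate
  absolute pressure.
- **Edge position** is the argmax *offset* (0–9, 9 = current sample)
  within the trailing 10 samples, earliest occurrence on ties.
- `dur_above_30`, `above_30_flag` and `pressure_abs` are intentionally not
  shift-invariant; every other feature is invariant under a constant
  pressure offset.
- Degenerate inputs: a constant window yields zero spectral power, mapped
  to frequency 0 and entropy/ratios 0; robust z-scores add 1e-6 to the
  denominator scale.

`feature_oracle` recomputes any single feature by a direct unvectorized
loop and exists purely as an independent check (tested to |Δ| ≤ 1e-8
against the vectorized path).

## Detector training (`detector`)

- **Case-wise split**: `split_cases` partitions case ids (default 80/20),
  at least one case per side; no case contributes samples to both sides.
- **Imbalance**: SMOTE implemented from its published definition —
  synthetic minority rows interpolated uniformly toward one of the k = 5
  nearest minority neighbors until classes balance (duplication fallback
  with a warning when the minority has < k+1 rows) — followed by
  appending factor−1 = 2 extra copies of each artifact row at ≥ 30 mmHg.
  Synthetic rows carry interpolated pressures. Resampling is applied
  inside training folds only; validation folds keep natural class ratios.
- **Hyperparameter search**: seeded random search (25 trials by default)
  over number of trees [50, 300], depth [3, 8], log-uniform learning rate
  [0.03, 0.3], and row/column subsampling [0.6, 1.0], maximizing mean
  artifact-class F1 across stratified 5-fold CV (fold seed 42). Resampled
  folds are built once and reused across trials. During the search each
  resampled fold is capped at 50,000 rows by stratified subsampling — a
  pure compute measure chosen so a 25-trial search on a full-scale cohort
  completes in minutes on one CPU; the final refit uses every row. Any
  argmax-over-trials strategy satisfies the objective; an adaptive
  optimizer can be swapped in behind the same interface.
- **Models**: LightGBM (primary), XGBoost, Random Forest, all with fixed
  seeds and single-threaded fits for determinism. Class weights stay at
  model defaults; imbalance is handled by resampling.
- **Bundles**: a saved detector is a zip of the pickled model plus JSON
  metadata (schema version, parameters, seeds, fold scores, post-processing
  parameters); loading restores bit-identical predictions.

## Post-processing (`postprocess`)

Stages: (1) centered rolling-median smoothing of probabilities (window 5,
edge-truncated — correction is retrospective, so centered smoothing is
acceptable); (2) threshold 0.5; (3) high-pressure guard: samples at
≥ 30 mmHg whose raw *or* smoothed probability reaches 0.3 are labeled;
(4) merge segments separated by ≤ 4 samples; (5) drop segments shorter
than 2 samples, except segments containing a guard sample, which survive
regardless of length. The guard precedes merging so rescued high-pressure
samples participate in morphological cleanup. Lowering the guard
threshold can only add labeled high-pressure samples (monotone).

The guard reads the unsmoothed probability deliberately: a genuine 1–2
sample contact spike at high pressure is detected with probability near 1
but flattened to ~0 by the median smoother, and a smoothed-only guard can
never see it — on synthetic benchmarks that single design detail accounted
for essentially all missed artifact time above 60 mmHg. For the same
reason the length filter exempts guard-rescued segments; at low pressure,
isolated single-sample detections are still treated as speckle and
removed.

The optimizer is a seeded random search (60 trials) over all five
parameters maximizing `F1 − λ·FN_hp`, where FN_hp is the false-negative
fraction among artifact samples at ≥ 30 mmHg and λ = 10 by default; the
default parameters are always trial zero, so optimization never returns
something worse than the defaults under the objective. A lexicographic
objective was rejected as brittle; λ makes the safety emphasis an explicit
trade-off. The weight matters because of scale: with a good detector
FN_hp sits around 0.01 — the same order as F1 differences between
reasonable parameter settings — so a unit weight reduces the objective to
plain F1 maximization and the search will happily trade a few missed
high-pressure samples for a marginal F1 gain. λ of order 10 makes the
safety term decisive exactly at the scale it takes values.

## Correction and exposure reporting (`correct_summarize`)

Exposure metrics use **exclusion** semantics: artifact samples are removed
and metrics computed over retained samples only. Linear interpolation
across removed intervals (nearest-retained fill at the edges) is used for
display traces only — duration metrics must not count interpolated filler.
Bins are left-closed right-open: [20,30), [30,40), [40,50), [50,60),
[60,80), [80,100), [100,∞); the headline "time > 30 mmHg" is strictly
greater-than as printed in clinical tables, so at exactly 30.000 mmHg the
two conventions can differ by one sample (0.25 s). Mean IRP averages all
retained samples including those below 20 mmHg. Note that exclusion also
removes the *true* pressure under each artifact, so on simulated data the
corrected time-above-threshold can fall below the clean signal's — the
same bias affects clinical ground-truth tables built by exclusion.

Cohort helpers compute medians/IQRs per metric, the reduction in median
peak pressure, the percent overestimation (100 × reduction / corrected
median), and the artifact share of a pressure stratum. Paired raw-vs-
corrected comparisons use the two-sided Wilcoxon signed-rank test (zero
differences dropped, mid-rank ties); with all-zero differences the test is
reported as undefined rather than given a fabricated p-value.

## Evaluation (`evaluate`)

Binary metrics (agreement in percent, recall, specificity, F1) are pooled
over samples from post-processed labels; AUC is rank-based from
pre-post-processing probabilities (post-processing is binary and would
degenerate the ROC). 95% CIs are percentile bootstrap over samples (1,000
replicates, seeded); for the binary metrics the bootstrap draws a
multinomial over the four confusion cells, which is distributionally
identical to resampling samples. Metrics are reported overall and on the
stratum of samples with raw pressure ≥ 30 mmHg. Error analysis reports
per-case cumulative seconds of missed artifact per pressure bin and the
fraction of missed artifact samples below 30 mmHg.

Feature attribution uses the tree libraries' exact tree-path Shapley
values (`pred_contrib`) for LightGBM/XGBoost and Saabas-style path
attributions for Random Forest (same additive decomposition, locally
credited); shares are mean |attribution| normalized to sum 1. Timing
reports wall-clock per case for extraction + prediction + post-processing,
excluding model loading; timings are hardware-dependent and informational
only.

## Benchmark protocol and problem sizes

The end-to-end benchmark simulates 27 full-scale cases (median ~16k
samples, ~500k samples total), splits them case-wise into 20 training and
7 test cases, further splits the 20 into 16 model-training and 4
internal-validation cases, tunes with 25 trials × 5 folds, refits, and
optimizes post-processing on the validation cases. Unit tests run the same
machinery on ~8× shortened cases (the generator preserves artifact density
under scaling); oracle-equivalence tests use 100 random traces of 300
samples. These sizes were chosen so the full suite and the benchmark each
complete in minutes on a single CPU while still exercising clinical-scale
inputs in the acceptance path.

## Known limitations

- The 25 unnamed features are declared stand-ins for an unpublished
  feature list; only the seven named features are anchored to the
  literature.
- The simulator matches aggregate medians/IQRs, not waveform realism;
  detector metrics on it are optimistic relative to clinical data (the
  synthetic task is more separable than expert-labeled recordings).
- The post-processing stage list and objective weighting reconstruct an
  unpublished design from its stated constraints.
- Non-4 Hz inputs are rejected, not resampled; all windows are defined in
  samples at 4 Hz.
- Real-time/streaming operation is out of scope (post-processing smoothing
  is centered).
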