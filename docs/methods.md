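# Methods

This note records the models, conventions and design decisions behind
`gaitstate`, in the order the pipeline applies them.

## Signal model and preprocessing

Recordings are tri-axial acceleration streams in g at a fixed sampling
frequency (default 32 Hz) from two knee-worn sensors saturating at ±8 g.
Values outside ±8 g are rejected under the strict policy or clipped under
the clip policy — never passed through silently. Timestamps, when present
in input files, are validated against the declared rate (median interval
within 1%) and discarded; the pipeline is index-based. Left and right knee
streams are treated as independently clocked; when their lengths differ
they are truncated to the shorter stream with a warning, never resampled.

Each axis is filtered with a fourth-order low-pass Butterworth at 15 Hz.
With a 16 Hz Nyquist this cutoff removes only a sliver of band; it is kept
as specified and an advisory is logged. The default mode is zero-phase
(forward–backward), because feature extraction is offline and phase lag
would bias gait-event timing; a causal single-pass mode is retained for
parity experiments, with step-response initial conditions so a constant
input stays constant. No gravity removal or axis reorientation is
performed; the 1 g baseline simply shifts the mean feature.

**Fold rule.** A course of *N* samples yields floor(*N*/320) full 320-sample
windows plus the trailing partial window iff it holds ≥ 160 samples —
equivalently round-half-up(*N*/320). This is the unique simple rule
consistent with all forty published per-course window counts the package
ships (remainders of 250 and 184 kept; 97 and 134 dropped). Features on a
partial window use its actual length as *n* throughout. Whether the
original study filtered before or after windowing is not stated; here the
whole course is filtered first, then windowed.

## Statistical features

All ten statistical features are computed on the per-sample Euclidean
magnitude of the window (one value per scalar feature per knee, matching
the published 16-features-per-knee layout), except the signal magnitude
area, which sums absolute values over the three axes as its formula
demands. Conventions, chosen where the printed formulas are ambiguous or
inconsistent and applied uniformly:

* standard deviation and the kurtosis moments use the population (1/N)
  normaliser; the skewness normaliser *s* is the sample (1/(n−1)) SD, as in
  the adjusted Fisher–Pearson coefficient n/((n−1)(n−2))·Σ((x−x̄)/s)³;
* kurtosis is standard excess kurtosis m₄/m₂² − 3 (a printed squared-SD
  denominator is dimensionally inconsistent and read as the fourth power);
* the IQR uses Tukey hinges — medians of the lower/upper halves, the
  overall median included in both halves for odd *n* — which reproduces the
  hand-checked example IQR(1..5) = 2;
* zero-variance and shorter-than-4-sample windows report skewness and
  kurtosis of 0 rather than NaN, so the feature matrix is always dense.

## Gait parameters

The source material quantifies the six spatiotemporal parameters by
reference to earlier work without formulas, so the estimator here is this
package's own, explicit stand-in:

1. **Cadence prior.** The dominant lag of the autocorrelation of the
   (mean-removed) magnitude series within a 0.4–3.2 s band. The upper lag
   must cover one stride at the slowest gait of interest (3.0 s at
   40 steps/min). Because a periodic train's autocorrelation peaks at every
   multiple of its period with near-equal height, the smallest local
   maximum within 85% of the band maximum is preferred over the raw argmax
   (fundamental preference). If the normalised peak height falls below
   0.2, the window is declared aperiodic: no gait events (white noise at
   n = 320 stays well below this gate; simulated gait and tremor sit far
   above it).
2. **Strike detection.** Candidate peaks are local maxima exceeding
   mean + 0.5·SD of the window; amplitude-priority suppression removes the
   smaller of any two candidates closer than half the estimated stride
   period. Surviving peaks are the instrumented leg's heel strikes, so
   inter-event intervals are stride times.
3. **Lengths.** Per stride, the vertical-axis acceleration is linearly
   detrended, converted g → m/s² (×9.81), integrated to velocity
   (detrended again to remove the unknown integration constant) and to
   displacement; *h* is the displacement range, averaged over strides and
   clipped at the leg length *l* (default 0.9 m, overridable per subject).
   The inverted-pendulum model gives step length 2√(2*l·h* − *h*²),
   monotone in *l* for *h* < *l*.

Symmetric gait is assumed: step time = stride time/2 and stride length =
2·step length by construction, so the velocity identities
(length/time) hold exactly. Windows with fewer than two detected strikes
emit zeros for all six parameters and carry a per-knee quality flag column.
All thresholds live in `GaitDetectorConfig`.

During tremor-dominated Off-state gait the detector can lock onto the
tremor periodicity rather than the stride, yielding a shorter
pseudo-stride time. This is a known behaviour of simple single-band
detectors; it is stable within a state and therefore still discriminative,
but the recovered Off-state gait parameters should not be read as
biomechanical truth.

## Classifiers, masks and partitioning

The four families use the published hyperparameters as frozen defaults:
random forest (500 trees, gini, max depth 8, min split 8, min leaf 10),
SVM (RBF kernel, C = 1, tol = 1e−3, gamma = 1/n_features — the legacy
"auto" setting), k-NN (50 neighbours, uniform weights, leaf size 40,
Euclidean Minkowski), Gaussian naive Bayes. The positive class is "On"
throughout. k-NN's neighbour count is clamped to the training-set size for
very small tables. SVM probability scores come from a Platt logistic map
fitted on out-of-fold decision values of the training set; its label
predictions are the SVM's own.

The packaged per-family feature masks reproduce the published
used/removed table verbatim (22 features kept for the random forest).
Recomputed masks use recursive feature elimination with step 1 down to the
packaged mask's size by default; families without a per-feature
importance notion (the RBF-SVM, k-NN, naive Bayes) fall back to a
univariate ANOVA-F ranking, which is logged.

Both partitioning schemes operate on subjects, never windows: the 70:30
split rounds 0.7·n_subjects (14/6 at n = 20) and LOSO yields one fold per
subject. A leakage assertion (no subject on both sides) runs inside every
evaluation path.

## Hyperparameter optimisation

Sequential model-based optimisation with a Gaussian-process surrogate
(constant × Matern-5/2 + white noise, normalised targets) over a unit-cube
encoding of the bounded search space. After n_init random evaluations
(default 8), each round fits the GP to all observations and evaluates the
candidate maximising the closed-form Gaussian expected improvement
(μ − f\*)Φ(z) + σφ(z), z = (μ − f\*)/σ, over a fresh 1024-point random
pool — pool-based acquisition avoids an inner optimiser. Failed objective
evaluations are recorded at the worst score observed so far and the search
continues. The search is deterministic given its seed. The objective
metric (held-out accuracy on a subject-level split) and the budget are
package defaults, not prescribed values.

## Evaluation conventions

Confusion cells follow the published per-subject table's orientation:
`fp` counts true-On windows called Off and `fn` true-Off windows called On,
so tp+fp is the On-window count and fn+tn the Off-window count. All rates
are derived from the cells under exactly this convention; "average"
recall/precision/F1 are macro (unweighted two-class) means — with the
near-balanced window counts macro and micro averages nearly coincide, but
the choice is fixed and documented. The diagnostic odds ratio applies the
Haldane–Anscombe +0.5 to all cells whenever any cell is zero; degenerate
denominators yield 0 with the report flagged. ROC-AUC is the rank-based
(Mann–Whitney) statistic with ties counted ½; its 95% CI is a
1000-resample percentile bootstrap at a fixed seed, since no CI method is
prescribed by the source material.

The packaged reference table reproduces the published per-subject rows
verbatim. Its printed Total row is internally inconsistent with those
rows: the per-subject tp column sums to 343 (printed total 342) and the
On-window counts to 374 (printed 373), while the Off side and the sample
totals (119,252 / 118,508 / 237,760) agree exactly. The package always
recomputes totals by summation; the regression tests document the
discrepancy rather than hiding it.

## Simulator

Each knee's vertical axis is a 1 g baseline plus a train of
Gaussian-windowed biphasic pulses (Gaussian-derivative shape, width ≈ 0.1
stride period) centred at that leg's strike times, plus an optional tremor
sinusoid and white sensor noise; the anterior–posterior and mediolateral
axes are scaled (0.55×, 0.35×), slightly time-shifted copies of the pulse
train with independent noise. Left and right strike trains are offset by
half a stride; stride intervals are normal with the configured CV
(truncated at 0.25 of the period). The packaged state contrast is: Off =
−20% cadence (80 vs 100 steps/min), −40% impulse amplitude (0.72 vs
1.2 g), 3× timing CV (0.15 vs 0.05) and a 5 Hz, 0.3 g tremor band; both
states share 210 s duration, 32 Hz sampling and 0.05 g noise SD. Cohorts
add per-subject random effects drawn once per subject — a normal cadence
offset (SD 6 steps/min) and a log-normal amplitude factor (log-SD 0.12) —
so LOSO folds carry genuine between-subject variance. Everything is
deterministic given one seed (per-course seeds are spawned from it).

What the simulator does **not** model: freezing of gait, turning,
non-walking activity, sensor drift or orientation error, asymmetric gait,
and any realistic biomechanical coupling between axes. Passing the
end-to-end discrimination tests therefore shows the pipeline correctly
senses the kind of cadence/amplitude/variability/tremor contrast the two
medication states are expected to produce — it is not evidence of
clinical-grade accuracy on real patients, whose recordings are not
publicly available.

## Problem sizes and numerical choices

The packaged end-to-end benchmark uses 20 subjects × two 210 s courses
(≈ 840 windows), the full study shape; unit-test fixtures use 6–8 subjects
at 60 s for speed. Filter correctness is checked against the analytic
Butterworth magnitude (1 + (f/f_c)^(2·order))^(−1/2) within 2%,
accommodating bilinear warping near the cutoff. Statistical features are
verified against direct formula evaluation to 1e−10 relative. The
null-separation control (identical On/Off generators) is tested as a
z-statistic over LOSO fold accuracies (|z| < 3), which respects the
within-subject correlation of windows. Stride-time recovery is required
within 5% of ground truth on jitter-free, tremor-free courses across
40–140 steps/min.

## Known limitations

* The gait-parameter estimator is a documented stand-in, not a validated
  biomechanical method; absolute step lengths depend on the leg-length
  default when no per-subject value is supplied.
* The step/stride distinction assumes symmetric gait measured from one
  leg's strikes; a knee sensor that reliably senses contralateral strikes
  would halve the measured intervals.
* The 15 Hz cutoff at a 16 Hz Nyquist leaves the filter nearly
  transparent; it is reproduced as specified rather than redesigned.
* RFE for the RBF-SVM uses the univariate fallback (no margin-based
  per-feature importance exists for a non-linear kernel).
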