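# Methods

This note documents the models, procedures and numerical choices behind
`gazedx`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design being modeled

The pipeline targets a two-visit diagnostic-accuracy design: children
aged 14–48 months referred to primary-care autism evaluation hubs
receive (a) a PCP diagnosis (autism / nonautism) with a certainty
rating dichotomized as certain vs uncertain, and (b) an expert
reference-standard diagnosis plus a five-paradigm eye-tracking battery.
The default cohort is 102 reference-autism and 44 nonautism children.
The analysis proceeds in three stages: per-marker screening, a
fixed-specificity composite index, and a decision-tree integration of
the index with the PCP's diagnosis and certainty.

## Synthetic cohort generator

The generator defines the study conditions for every downstream test.

- **Biomarkers.** Each of the six candidate biomarkers is drawn, per
  group, from a normal distribution truncated to the observed range
  (rejection sampling; `sd = 0` degenerates to the constant mean).
  Means/SDs/ranges are the published group statistics, e.g. nonsocial
  preference 46.20 (22.33) [3.35, 86.80] in autism vs 21.50 (12.48)
  [0.62, 56.72] in nonautism. Auxiliary metrics (overlap-gap RT, tonic
  pupil, saccade amplitude/duration) were not discriminative in the
  source cohort; their generator values are plausible, largely
  overlapping choices documented in `cohort.TABLE_DISTRIBUTIONS`.
- **Missingness.** Task-level, independent across children and tasks; a
  missing task blanks all metrics it produces ("missing data are never
  imputed" downstream). Default rates per task (geopref .06,
  gap-overlap .25, PLR .40, resting .10, exploration .20) sit inside
  the reported 50–94% usable-data range; per-task rates were not
  published.
- **PCP labels.** P(dx = autism | autism) = 71/102 and
  P(dx = nonautism | nonautism) = 36/44, the margins implied by the
  published decision-tree counts. Certainty is Bernoulli conditional on
  correctness with P(certain | correct) = 0.75 and
  P(certain | incorrect) = 0.40 — assumed values (only the direction,
  "accuracy covaries with certainty", is reported) fixed once.
- **Clinical scores.** MSEL ELC, VABS-3 ABC and ADOS-2 CSS follow the
  published group statistics; MSEL and VABS are coupled to nonsocial
  preference within group at ρ = −0.30 via a Gaussian-score mixture
  (range-clipped), emulating the reported associations.
- **Demographics.** Age uniform on [14, 48] months; sex 71%/29%
  male/female. One `numpy` generator per run, seeded from
  `SimulationSpec.seed`; the seed is recorded in output metadata.

## Raw gaze-stream synthesis

Streams (default 120 Hz; columns time, x°, y°, pupil mm, validity) are
rendered from latent per-child parameters with isotropic Gaussian
fixation jitter (default SD 0.08°, chosen so a 1°-dispersion detector
never splits a rendered fixation; pupil noise is coupled at 0.01 mm per
degree so `noise_sd=0` is fully noiseless).

Discrete sampling quantizes some latent values — latencies to the
sample grid, no-shift percentages to whole trials. Every renderer
therefore reports the *realized* ground truth alongside the stream, and
`render_cohort_streams` writes realized values back into the cohort
table, so recovery is always measured against what the streams actually
contain. Task defaults (configurable): 30 s preference viewing, 20
gap + 20 overlap trials of 1.6 s with target onset at 400 ms, 4 PLR
trials of 3.5 s with the flash at 1 s, 30 s resting and 20 s
exploration viewing. The gap-overlap renderer needs a baseline the
difference metrics do not pin down; it assumes a 300 ms gap-condition
RT and a 10% gap-condition no-shift rate.

What the generator does **not** emulate: real stimulus content and
luminance, smooth pursuit, head motion, blink dynamics (validity gaps
are supported but not rendered by default), binocular disparity, and
any dependence structure of missingness across tasks. Passing recovery
tests therefore show the *extraction pipeline* is correct and unbiased
under these idealized conditions, not that the thresholds are optimal
for any particular tracker.

## Event detection and quality control

Fixations use the dispersion-threshold algorithm (I-DT): maximal runs
with (max−min x) + (max−min y) ≤ 1.0° spanning ≥ 100 ms. Invalid gaps
≤ 75 ms are bridged by linear interpolation (blink robustness); longer
gaps split the stream, and no saccade is formed across a split. All
three constants are arguments. Saccades are defined between adjacent
fixations: amplitude = centroid distance, duration = inter-fixation
gap. Accuracy is the angular offset of the valid-sample centroid from a
drift-check target; precision is the RMS of successive sample-to-sample
distances within fixations, pooled per child (a centroid-based variant
exists but is not the default, matching the successive-distance
definition).

## Biomarker extraction

- **Nonsocial preference** = 100 × dwell(nonsocial AOI) / dwell(both
  AOIs); samples outside both AOIs are excluded from the denominator.
- **Gap–overlap**: per-trial RT is the first sample inside the target
  AOI after onset, valid in [100, 1000] ms; earlier shifts are
  anticipatory and discard the trial; no qualifying shift within 1 s is
  a no-shift trial. `overlap_gap_rt` = mean RT(overlap) − mean RT(gap).
  The **no-shift gap effect** is read as the signed overlap-minus-gap
  difference in no-shift percentages: the published range of this
  metric spans negative values, which a single-condition percentage
  cannot produce. This reading is a documented interpretation.
- **PLR**: baseline = mean pupil over the 200 ms before the flash;
  constriction onset = the sample preceding the first run of ≥ 3
  samples whose trailing-moving-average (50 ms) velocity is below
  −0.3 mm/s; amplitude = 100 × (baseline − minimum) / baseline. All
  constants are arguments. On noiseless aligned traces the onset
  definition recovers the latency exactly; for very shallow
  constrictions (amplitude × baseline small) the sustained-run rule can
  report one sample late, which is within the stated one-sample-period
  recovery tolerance.
- **Summaries**: arithmetic means of event durations/amplitudes and of
  valid pupil samples (tonic pupil). A task is usable when its
  valid-sample fraction meets an inclusive 0.5 threshold.

## Screening

Plain maximum-likelihood logistic regression (statsmodels `Logit`), no
penalization; complete-case per model. Odds ratios are per unit of the
marker's native scale (per %, per ms), age is entered in years, sex as
a male indicator. Wald χ² = (β̂/SE)². Separation or non-convergence is
flagged on the result object rather than silently repaired. AUC is the
Mann–Whitney concordance with half credit for ties; for a univariate
fit with positive slope it equals the raw-marker AUC (asserted as a
property). Clinical correlations report Pearson r with Fisher-z 95%
CIs and the n of complete pairs, flagged at α = .05/3 ≈ .0167.

## Composite index

For each marker, with direction fixed by the group means (low-positive
for PLR latency, high-positive otherwise), the threshold is the k-th
order statistic of the nonautism values with k = ⌈0.95 n⌉, i.e. the
least extreme observed value keeping strict-exceedance false positives
≤ 5%. Ties at the threshold are negative (specificity-first), missing
markers are negative, the composite is positive iff any flag is set,
and biomarker frequency is the number of set flags (0–6). Cutoffs are
derived on the full sample, as in a derivation cohort; a split-sample
path is available through ordinary subsetting but is not the default.
Wilson score intervals are the default CI family — they reproduce the
published bounds for the worked examples, which exact Clopper–Pearson
does not — with Clopper–Pearson behind a flag. Cohen's κ uses the
asymptotic SE √(p₀(1−p₀)/(n(1−p_e)²)).

## Decision tree

Greedy binary recursive partitioning on Gini impurity (entropy
available); the frontier leaf with the largest achievable gain is split
first; growth stops after `max_splits` (default 5) splits or when no
split gains ≥ `min_gain` (default 0.005, which keeps a genuinely
uninformative feature from splitting at n = 1000); leaves keep
≥ `min_node` (default 5) cases. Ties break on a fixed variable order
(composite, frequency, eae_dx, certainty) then the lower threshold, so
fitting is deterministic. The terminal decision policy
(diagnose / rule out / refer) is explicit configuration: the published
assignment refers one terminal whose class purity (75% nonautism)
matches another that is decided (74% nonautism), so no purity threshold
can derive it — it encodes clinical judgment. Evaluation excludes
referred cases and scores the rest against the reference labels.
Cross-validation is stratified k-fold (seeded, recorded in the report);
held-out cases are scored by the training tree's terminal autism
posterior. The exact split statistic of the original analysis software
is not published; structural agreement is asserted only on synthetic
data, and the published tree itself is stored with its printed counts.

## Problem sizes and tolerances

Defaults were chosen as round, adequately powered sizes: distributional
checks use 10 000 draws per group against truncation-adjusted
truncated-normal moments (3 SE); the end-to-end recovery check renders
the full 146-child cohort and requires each group's extracted biomarker
mean within 5% of the rendered ground truth; oracle equivalences
(exhaustive maximal-run fixation search, all-pairs AUC counting,
logistic grid search) run on inputs up to a few hundred points where
brute force is exact; permutation uniformity uses 1000 label shuffles.

## Known limitations

- The composite's cutoffs and the tree are derived and evaluated on the
  same sample by default (as in the source analysis); reported
  accuracies are therefore optimistic relative to out-of-sample use.
- Real-data quantities that depend on the study's raw recordings
  (per-marker ORs/AUCs as point values, the fitted tree's real-data
  AUC) are reproducible only in direction and rough magnitude from the
  synthetic cohort, not as point values.
- Monocular vs binocular pupil handling is unspecified upstream; the
  pipeline treats the pupil trace as a single signal.
- The no-shift gap effect's signed-difference reading and the PCP
  certainty rates are documented interpretations/assumptions (see
  above), fixed once and not tuned.
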