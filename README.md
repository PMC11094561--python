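# gazedx

Eye-tracking biomarkers and composite diagnostic indexing for early
autism evaluation in primary care.

## The problem

Most young children referred for an autism evaluation wait many months
for a specialist, while primary-care practitioners (PCPs) trained to
make the diagnosis themselves are accurate mainly when they are
*certain*. Eye tracking offers objective, low-cost biomarkers — autistic
toddlers tend to show, among other things, a stronger preference for
geometric over social motion, slower attentional disengagement, a
faster and deeper pupillary light reflex (PLR), and longer fixations.
`gazedx` implements a complete analysis pipeline for this setting, for
researchers studying multi-marker diagnostic batteries and for
methodologists evaluating tiered diagnostic models:

1. **Synthetic cohorts and raw gaze streams** with known ground truth
   (102 autism / 44 nonautism children by default, group-conditional
   truncated-normal biomarkers, task-level missingness, PCP labels whose
   accuracy covaries with rated certainty).
2. **Gaze signal processing** — dispersion-threshold (I-DT) fixation
   detection, saccade extraction, drift-check accuracy and RMS
   precision.
3. **Biomarker extraction** for five paradigms: nonsocial preference %,
   gap–overlap RT difference and no-shift gap effect, PLR latency and
   amplitude, resting/exploration fixation durations, tonic pupil size.
4. **Screening** — per-marker logistic regression (OR per unit, Wald
   χ², AUC; age/sex-adjusted models), Pearson correlations with
   clinical scores (Fisher-z CIs, Bonferroni α = .0167).
5. **Composite index** — for each marker the cut point *c* is the least
   extreme value with specificity ≥ 0.95 in the nonautism group; a
   child is biomarker-positive iff any of the six markers strictly
   exceeds its cut point (missing ⇒ negative). Accuracy is reported as
   sensitivity/specificity/PPV/NPV with Wilson 95% CIs and Cohen's κ
   with the asymptotic CI κ ± 1.96·√(p₀(1−p₀)/(n(1−p_e)²)).
6. **Decision tree** — CART (Gini, best-gain-first, fixed split budget)
   over {composite, biomarker frequency, PCP diagnosis, certainty},
   with three-way terminal decisions **diagnose / rule out / refer**,
   evaluation over decided cases, and stratified 5-fold
   cross-validation. The published tree and its decision policy are
   available as a worked example.

## Worked example

The reported decision tree, applied to its stored node counts with the
published three-way decision policy:

```python
from gazedx import published_tree, PUBLISHED_POLICY, evaluate_decided

stats, referred = evaluate_decided(published_tree(), PUBLISHED_POLICY)
print(referred, stats.n, stats.concordant)
print(f"{100*stats.sensitivity:.1f} {100*stats.specificity:.1f} "
      f"{100*stats.ppv:.1f} {100*stats.npv:.1f} {stats.kappa:.2f}")
```

prints

```
19 127 114
90.7 86.7 95.7 74.3 0.73
```

— 19 of 146 children are referred to a specialist; of the 127 decided
cases, 114 agree with the expert reference diagnosis (sensitivity
90.7%, specificity 86.7%, PPV 95.7%, NPV 74.3%, κ = 0.73). The
composite biomarker alone (any of six markers beyond its
95%-specificity cutoff) reaches 77.5% sensitivity and 77.3% specificity
on the corresponding confusion counts; integrating it with PCP
diagnosis and certainty is what buys the extra accuracy at the price of
referring ~13% of cases.

The `examples/` directory holds one short script per capability
(cohort simulation, event detection and QC, screening, composite
indexing, decision trees, and the full pipeline); each prints the
numbers it computes and a line on what they mean. The same pipeline is
scriptable from the shell:

```bash
gazedx run --seed 1 --out-dir demo_run     # full pipeline, all artifacts
gazedx cart --paper-tree --out cart.json   # published-tree worked example
```

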