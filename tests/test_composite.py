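"""Fixed-specificity cutoffs, the any-positive composite, and the
diagnostic-accuracy statistics (Wilson CIs, Cohen's kappa)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gazedx.cohort import BIOMARKERS, SimulationSpec, simulate_biomarker_table
from gazedx.composite import (
    Confusion2x2,
    accuracy_stats,
    binarize_and_compose,
    cohen_kappa,
    compose_table,
    confusion_from_labels,
    derive_all_cutoffs,
    derive_cutoff,
    wilson_ci,
)


def cutoff_brute_force(values_nonautism, direction, target):
    """Try every observed value as threshold; keep the least extreme one
    whose strict-exceedance false-positive rate is within 1 - target."""
    v = np.asarray(values_nonautism, float)
    v = v[np.isfinite(v)]
    n = len(v)
    best = None
    for thr in np.sort(v):
        fp = np.sum(v > thr) if direction == "high_is_positive" else np.sum(v < thr)
        if fp / n <= 1 - target:
            if direction == "high_is_positive":
                best = thr if best is None else min(best, thr)
            else:
                best = thr if best is None else max(best, thr)
    return best


class TestDeriveCutoff:
    def test_uniform_1_to_100(self):
        rule = derive_cutoff([], np.arange(1, 101), "high_is_positive")
        assert rule.threshold == 95
        assert rule.achieved_specificity == pytest.approx(0.95)

    def test_target_one_gives_max(self):
        v = np.arange(1, 101)
        rule = derive_cutoff([], v, "high_is_positive", target_specificity=1.0)
        assert rule.threshold == 100
        assert rule.achieved_specificity == 1.0

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(0)
        v = rng.normal(10, 3, 200)
        hi = derive_cutoff([], v, "high_is_positive")
        lo = derive_cutoff([], -v, "low_is_positive")
        assert lo.threshold == pytest.approx(-hi.threshold)
        assert lo.achieved_specificity == pytest.approx(hi.achieved_specificity)

    @pytest.mark.parametrize("seed,n", [(0, 23), (1, 44), (2, 500), (3, 10_000)])
    @pytest.mark.parametrize("direction", ["high_is_positive", "low_is_positive"])
    def test_matches_brute_force(self, seed, n, direction):
        rng = np.random.default_rng(seed)
        v = np.round(rng.normal(50, 12, n), 1)  # ties occur
        rule = derive_cutoff([], v, direction)
        assert rule.threshold == pytest.approx(
            cutoff_brute_force(v, direction, 0.95))
        assert rule.achieved_specificity >= 0.95

    def test_degenerate_flagged(self):
        rule = derive_cutoff([], np.full(20, 7.0), "high_is_positive")
        assert rule.degenerate
        assert rule.achieved_specificity == 1.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            derive_cutoff([], [1, 2, 3], "high_is_positive")
        with pytest.raises(ValueError, match="direction"):
            derive_cutoff([], np.arange(10), "sideways")


class TestCompose:
    def rules(self):
        table = simulate_biomarker_table(SimulationSpec(seed=1))
        return derive_all_cutoffs(table)

    def test_all_missing_is_negative(self):
        rules = self.rules()
        res = binarize_and_compose({b: float("nan") for b in BIOMARKERS}, rules)
        assert res.frequency == 0 and not res.positive

    def test_single_exceedance_is_positive(self):
        rules = self.rules()
        vals = {b: float("nan") for b in BIOMARKERS}
        r = rules["nonsocial_preference_pct"]
        vals["nonsocial_preference_pct"] = r.threshold + 1.0
        res = binarize_and_compose(vals, rules)
        assert res.frequency == 1 and res.positive

    def test_tie_at_threshold_is_negative(self):
        rules = self.rules()
        for b, r in rules.items():
            vals = {k: float("nan") for k in BIOMARKERS}
            vals[b] = r.threshold  # exactly at the cut point
            assert not binarize_and_compose(vals, rules).positive

    def test_table_compose_matches_rowwise(self):
        table = simulate_biomarker_table(SimulationSpec(seed=5))
        rules = derive_all_cutoffs(table)
        composed = compose_table(table, rules)
        for i, (_, row) in enumerate(table.iterrows()):
            res = binarize_and_compose({b: row[b] for b in BIOMARKERS}, rules)
            assert composed["biomarker_frequency"].iloc[i] == res.frequency
            assert bool(composed["composite_positive"].iloc[i]) == res.positive
        assert (composed["biomarker_frequency"]
                == sum(composed[f"flag_{b}"] for b in BIOMARKERS)).all()


class TestAccuracyStats:
    def test_perfect_table(self):
        s = accuracy_stats(Confusion2x2(tp=40, fp=0, fn=0, tn=20))
        assert s.sensitivity == 1.0 and s.specificity == 1.0
        assert s.ppv == 1.0 and s.npv == 1.0
        assert s.kappa == pytest.approx(1.0)

    def test_independence_table_kappa_zero(self):
        # margins: test 30/30, reference 30/30, counts at independence
        s = accuracy_stats(Confusion2x2(tp=15, fp=15, fn=15, tn=15))
        assert s.kappa == pytest.approx(0.0)

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(2)
        test = rng.random(300) < 0.4
        ref = rng.random(300) < 0.6
        table = confusion_from_labels(test, ref)
        assert table.tp == int(np.sum(test & ref))
        assert table.n == 300
        s = accuracy_stats(table)
        assert s.sensitivity == pytest.approx(np.sum(test & ref) / np.sum(ref))
        assert s.concordant == int(np.sum(test == ref))

    def test_empty_margin_missing(self):
        s = accuracy_stats(Confusion2x2(tp=0, fp=5, fn=0, tn=5))
        assert np.isnan(s.sensitivity)
        assert np.isfinite(s.specificity)


class TestWilson:
    def test_zero_successes_lower_bound_zero(self):
        lo, hi = wilson_ci(0, 10)
        assert lo == pytest.approx(0.0)
        assert 0 < hi < 0.35

    def test_reported_bounds(self):
        lo, hi = wilson_ci(79, 102)
        assert (round(100 * lo, 1), round(100 * hi, 1)) == (68.4, 84.5)
        lo, hi = wilson_ci(34, 44)
        assert (round(100 * lo, 1), round(100 * hi, 1)) == (63.0, 87.2)

    def test_clopper_pearson_available_and_wider(self):
        w = wilson_ci(79, 102)
        cp = wilson_ci(79, 102, method="beta")
        assert cp[0] < w[0] or cp[1] > w[1]

    def test_n_zero_missing(self):
        assert all(np.isnan(v) for v in wilson_ci(0, 0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 50), st.integers(1, 50))
    def test_interval_contains_point_estimate(self, k, n):
        k = min(k, n)
        lo, hi = wilson_ci(k, n)
        assert 0.0 <= lo <= k / n <= hi <= 1.0


class TestCompositeInvariants:
    def test_union_bounds_and_expected_specificity(self):
        """The any-positive composite can only add detections (sensitivity
        >= each marker's) and false alarms (specificity <= each marker's);
        with six independent markers cut at 95% specificity the composite
        specificity is near 0.95**6 ~ 0.735."""
        spec = SimulationSpec(
            n_autism=2000, n_nonautism=2000, seed=10,
            missingness_rate_per_task={t: 0.0 for t in
                                       ("geopref", "gap_overlap", "plr",
                                        "resting", "exploration")},
        )
        table = simulate_biomarker_table(spec)
        rules = derive_all_cutoffs(table)
        composed = compose_table(table, rules)
        ref = (table["group"] == "autism").to_numpy()
        comp_pos = composed["composite_positive"].to_numpy().astype(bool)
        comp = accuracy_stats(confusion_from_labels(comp_pos, ref))
        for b in BIOMARKERS:
            marker = accuracy_stats(
                confusion_from_labels(composed[f"flag_{b}"].astype(bool), ref))
            assert comp.sensitivity >= marker.sensitivity - 1e-12
            assert comp.specificity <= marker.specificity + 1e-12
            assert marker.specificity >= 0.95
        assert comp.specificity == pytest.approx(0.95**6, abs=0.04)

    def test_achieved_specificity_at_least_target_by_construction(self, cohort_table):
        rules = derive_all_cutoffs(cohort_table)
        for b, rule in rules.items():
            non = cohort_table.loc[cohort_table.group == "nonautism", b].dropna()
            if rule.direction == "high_is_positive":
                fp = (non > rule.threshold).sum()
            else:
                fp = (non < rule.threshold).sum()
            assert 1 - fp / len(non) >= 0.95
            assert rule.achieved_specificity == pytest.approx(1 - fp / len(non))


def test_kappa_reported_ci_formula():
    kappa, (lo, hi) = cohen_kappa(Confusion2x2(79, 10, 23, 34))
    assert (round(lo, 2), round(hi, 2)) == (0.36, 0.65)
    assert kappa == pytest.approx(0.5048, abs=1e-4)
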