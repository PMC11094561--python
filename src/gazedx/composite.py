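"""Stage-2: fixed-specificity cutoffs, the any-positive composite
biomarker, and diagnostic-accuracy statistics.

Because autism phenotypes are heterogeneous and overlap with other
neurodevelopmental conditions, each biomarker's cut point is chosen to
achieve at least 95% specificity in the nonautism group, and a child is
*biomarker-positive* if any of the six markers strictly exceeds its
cutoff (in the marker's direction of risk).  Biomarker frequency is the
number of exceeded cutoffs (0-6).  Missing markers are never imputed: a
child with no usable data for a task is assumed not to exceed that
task's cutoffs.  Ties at the threshold count as negative (strict
exceedance), which favors specificity.

Accuracy indices (sensitivity, specificity, PPV, NPV) carry Wilson
score 95% CIs — the interval family that reproduces the study's printed
bounds — with Clopper-Pearson available by flag.  Chance-corrected
agreement is Cohen's kappa with the asymptotic CI
``kappa +/- 1.96 * sqrt(p0 (1 - p0) / (n (1 - pe)^2))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .cohort import BIOMARKERS

__all__ = [
    "CutoffRule",
    "CompositeResult",
    "Confusion2x2",
    "AccuracyStats",
    "MARKER_DIRECTIONS",
    "derive_cutoff",
    "derive_all_cutoffs",
    "binarize_and_compose",
    "compose_table",
    "wilson_ci",
    "cohen_kappa",
    "accuracy_stats",
    "confusion_from_labels",
]

#: Direction of risk per marker, fixed from the group means: autism shows
#: higher nonsocial preference, no-shift gap effect, fixation durations and
#: PLR amplitude, but *shorter* PLR latency.
MARKER_DIRECTIONS = {
    "nonsocial_preference_pct": "high_is_positive",
    "no_shift_gap_effect_pct": "high_is_positive",
    "resting_fixation_duration_ms": "high_is_positive",
    "plr_latency_ms": "low_is_positive",
    "plr_amplitude_pct": "high_is_positive",
    "exploration_fixation_duration_ms": "high_is_positive",
}


@dataclass(frozen=True)
class CutoffRule:
    """Direction-aware threshold achieving a target specificity."""

    biomarker_name: str
    direction: str  # high_is_positive | low_is_positive
    threshold: float
    achieved_specificity: float
    target_specificity: float = 0.95
    degenerate: bool = False

    def is_positive(self, value) -> bool:
        """Strict exceedance; missing values are negative."""
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return False
        if self.direction == "high_is_positive":
            return bool(value > self.threshold)
        return bool(value < self.threshold)


@dataclass(frozen=True)
class CompositeResult:
    flags: dict  # biomarker -> 0/1
    frequency: int
    positive: bool


@dataclass(frozen=True)
class Confusion2x2:
    tp: int
    fp: int
    fn: int
    tn: int
    referred: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class AccuracyStats:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    kappa: float
    kappa_ci: tuple
    concordant: int
    n: int
    ci: dict = field(default_factory=dict)  # index -> (low, high)

    def to_dict(self) -> dict:
        d = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "kappa": self.kappa,
            "kappa_ci_low": self.kappa_ci[0],
            "kappa_ci_high": self.kappa_ci[1],
            "concordant": self.concordant,
            "n": self.n,
        }
        for k, (lo, hi) in self.ci.items():
            d[f"{k}_ci_low"] = lo
            d[f"{k}_ci_high"] = hi
        return d


def derive_cutoff(
    values_autism,
    values_nonautism,
    direction: str,
    biomarker_name: str = "",
    target_specificity: float = 0.95,
) -> CutoffRule:
    """Least extreme threshold with nonautism positives <= 1 - target.

    The threshold is an observed nonautism value; a child is positive
    when strictly beyond it.  Choosing the least extreme qualifying
    value maximizes sensitivity subject to the specificity floor.
    Missing values are ignored.  All-identical nonautism values yield a
    degenerate (flagged) rule at that value.
    """
    if direction not in ("high_is_positive", "low_is_positive"):
        raise ValueError(f"unknown direction {direction!r}")
    vn = np.asarray(values_nonautism, float)
    vn = vn[np.isfinite(vn)]
    if len(vn) < 5:
        raise ValueError("need at least 5 nonautism values to derive a cutoff")
    n = len(vn)
    vs = np.sort(vn)
    if vs[0] == vs[-1]:
        return CutoffRule(biomarker_name, direction, float(vs[0]), 1.0,
                          target_specificity, degenerate=True)
    # k = number of nonautism values that must lie on the negative side
    k = int(np.ceil(target_specificity * n))
    if direction == "high_is_positive":
        thr = float(vs[k - 1])  # k-th smallest; positives are > thr
        n_pos = int(np.sum(vn > thr))
    else:
        thr = float(vs[n - k])  # k-th largest; positives are < thr
        n_pos = int(np.sum(vn < thr))
    return CutoffRule(
        biomarker_name, direction, thr,
        achieved_specificity=1.0 - n_pos / n,
        target_specificity=target_specificity,
    )


def derive_all_cutoffs(
    table: pd.DataFrame,
    biomarkers=None,
    directions: dict | None = None,
    target_specificity: float = 0.95,
    group_col: str = "group",
) -> dict:
    """Derive one cutoff rule per biomarker from the cohort table."""
    biomarkers = list(biomarkers) if biomarkers is not None else BIOMARKERS
    directions = directions or MARKER_DIRECTIONS
    rules = {}
    aut = table[table[group_col] == "autism"]
    non = table[table[group_col] == "nonautism"]
    for b in biomarkers:
        rules[b] = derive_cutoff(
            aut[b], non[b], directions[b], biomarker_name=b,
            target_specificity=target_specificity,
        )
    return rules


def binarize_and_compose(biomarkers: dict, rules: dict) -> CompositeResult:
    """Apply the six cutoff rules to one child's biomarker values.

    Missing values never flag positive; the composite is positive iff
    any flag is set, and frequency is the number of set flags.
    """
    flags = {name: int(rule.is_positive(biomarkers.get(name))) for name, rule in rules.items()}
    freq = int(sum(flags.values()))
    return CompositeResult(flags=flags, frequency=freq, positive=freq >= 1)


def compose_table(table: pd.DataFrame, rules: dict) -> pd.DataFrame:
    """Per-child composite flags/frequency/positivity for a cohort table."""
    out = table[["child_id"]].copy() if "child_id" in table else pd.DataFrame(index=table.index)
    freq = np.zeros(len(table), dtype=int)
    for name, rule in rules.items():
        v = table[name]
        if rule.direction == "high_is_positive":
            flag = (v > rule.threshold).fillna(False)
        else:
            flag = (v < rule.threshold).fillna(False)
        out[f"flag_{name}"] = flag.astype(int).to_numpy()
        freq += out[f"flag_{name}"].to_numpy()
    out["biomarker_frequency"] = freq
    out["composite_positive"] = (freq >= 1).astype(int)
    return out


def wilson_ci(successes: int, n: int, level: float = 0.95, method: str = "wilson"):
    """Wilson score interval for a binomial proportion.

    ``method="beta"`` switches to exact Clopper-Pearson.
    """
    if n == 0:
        return (float("nan"), float("nan"))
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method=method)
    lo = 0.0 if successes == 0 else float(np.clip(lo, 0.0, 1.0))
    hi = 1.0 if successes == n else float(np.clip(hi, 0.0, 1.0))
    return (lo, hi)


def cohen_kappa(table: Confusion2x2, z: float = 1.959963984540054):
    """Cohen's kappa for a 2x2 agreement table, with asymptotic 95% CI."""
    n = table.n
    if n == 0:
        return float("nan"), (float("nan"), float("nan"))
    p0 = (table.tp + table.tn) / n
    pe = (
        (table.tp + table.fp) * (table.tp + table.fn)
        + (table.fn + table.tn) * (table.fp + table.tn)
    ) / n**2
    if pe == 1.0:
        return float("nan"), (float("nan"), float("nan"))
    kappa = (p0 - pe) / (1 - pe)
    se = np.sqrt(p0 * (1 - p0) / (n * (1 - pe) ** 2))
    return float(kappa), (float(kappa - z * se), float(kappa + z * se))


def accuracy_stats(table: Confusion2x2, ci_method: str = "wilson") -> AccuracyStats:
    """Sensitivity/specificity/PPV/NPV with 95% CIs, kappa, concordance."""
    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    ci = {}
    for name, (num, den) in {
        "sensitivity": (tp, tp + fn),
        "specificity": (tn, tn + fp),
        "ppv": (tp, tp + fp),
        "npv": (tn, tn + fn),
    }.items():
        ci[name] = wilson_ci(num, den, method=ci_method) if den > 0 else (float("nan"),) * 2
    kappa, kci = cohen_kappa(table)
    return AccuracyStats(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        kappa=kappa, kappa_ci=kci, concordant=tp + tn, n=table.n, ci=ci,
    )


def confusion_from_labels(test_positive, reference_positive) -> Confusion2x2:
    """Count a 2x2 table from per-child binary labels."""
    t = np.asarray(test_positive).astype(bool)
    r = np.asarray(reference_positive).astype(bool)
    return Confusion2x2(
        tp=int(np.sum(t & r)),
        fp=int(np.sum(t & ~r)),
        fn=int(np.sum(~t & r)),
        tn=int(np.sum(~t & ~r)),
    )
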