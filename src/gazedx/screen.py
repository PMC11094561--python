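"""Stage-1 statistics: per-biomarker logistic screening, ROC/AUC, and
clinical correlations.

Each candidate biomarker is screened against the reference-standard
diagnosis with a binary logistic regression (unadjusted, then adjusted
for age in years and sex), reporting the per-unit odds ratio with 95%
CI, the Wald chi-square, and the AUC of the fitted score.  Missing
predictor values are dropped per model (complete-case analysis; no
imputation).  Complete separation or non-convergence is flagged on the
result, never silently "fixed".

Correlations between biomarkers and standardized clinical scores use
Pearson r with Fisher-z 95% CIs, flagged for significance at the
Bonferroni-adjusted threshold alpha = .05 / 3 = .0167 (three clinical
scales per biomarker family).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import BIOMARKERS

__all__ = [
    "LogisticFit",
    "CorrelationResult",
    "fit_logistic",
    "roc_auc",
    "clinical_correlations",
    "screen_biomarkers",
    "BONFERRONI_ALPHA",
]

BONFERRONI_ALPHA = 0.05 / 3  # three clinical scales per biomarker


@dataclass
class PredictorEffect:
    name: str
    coef: float
    se: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    wald_chi2: float
    p_value: float


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit of diagnosis on predictors."""

    intercept: float
    effects: dict = field(default_factory=dict)  # name -> PredictorEffect
    auc: float = float("nan")
    n_used: int = 0
    converged: bool = True
    separation: bool = False

    @property
    def flagged(self) -> bool:
        return self.separation or not self.converged


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    alpha: float = BONFERRONI_ALPHA

    @property
    def significant_after_bonferroni(self) -> bool:
        return bool(np.isfinite(self.p_value) and self.p_value < self.alpha)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve of ``scores`` against binary ``labels``.

    Equal to the Mann-Whitney concordance probability
    ``P(score_pos > score_neg) + 0.5 * P(tie)``.  Returns NaN when a
    class is absent.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    ok = np.isfinite(scores)
    scores, labels = scores[ok], labels[ok]
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def fit_logistic(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: tuple = (),
    z: float = 1.959963984540054,
) -> LogisticFit:
    """Fit a binary logistic regression of ``outcome`` on one biomarker.

    ``outcome`` must be a column of 0/1 (or boolean) labels; rows with a
    missing predictor or covariate are dropped.  Wald chi-square is
    ``(coef / se)**2`` with a two-sided normal p-value; odds ratios are
    per unit of the predictor's native scale.
    """
    cols = [outcome, predictor, *covariates]
    d = data[cols].dropna()
    y = d[outcome].astype(float).to_numpy()
    if len(np.unique(y)) < 2 or (y == y[0]).all():
        raise ValueError("outcome must contain both classes")
    X = d[[predictor, *covariates]].astype(float)
    if (X.nunique() <= 1).any():
        raise ValueError("constant predictor column")
    X = sm.add_constant(X, prepend=True)

    fit = LogisticFit(intercept=float("nan"), n_used=len(d))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        fit.converged = False
        fit.separation = True
        return fit

    fit.converged = bool(res.mle_retvals.get("converged", False))
    # near-separation shows up as exploding standard errors
    if not np.all(np.isfinite(res.bse)) or np.any(np.asarray(res.bse) > 1e6):
        fit.separation = True
    fit.intercept = float(res.params.iloc[0])
    for name in [predictor, *covariates]:
        coef = float(res.params[name])
        se = float(res.bse[name])
        wald = (coef / se) ** 2 if se > 0 else float("inf")
        p = 2 * sps.norm.sf(abs(coef / se)) if se > 0 else 0.0
        with np.errstate(over="ignore"):  # huge CIs under near-separation
            fit.effects[name] = PredictorEffect(
                name=name,
                coef=coef,
                se=se,
                odds_ratio=float(np.exp(coef)),
                or_ci_low=float(np.exp(coef - z * se)),
                or_ci_high=float(np.exp(coef + z * se)),
                wald_chi2=float(wald),
                p_value=float(p),
            )
    fit.auc = roc_auc(res.predict(X), y.astype(bool))
    return fit


def pearson_fisher_ci(x, y, z: float = 1.959963984540054):
    """Pearson r with a Fisher-z 95% CI over complete pairs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 4:
        return CorrelationResult(float("nan"), float("nan"), float("nan"), float("nan"), n)
    r, p = sps.pearsonr(x[ok], y[ok])
    zr = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = z / np.sqrt(n - 3)
    return CorrelationResult(
        r=float(r),
        ci_low=float(np.tanh(zr - half)),
        ci_high=float(np.tanh(zr + half)),
        p_value=float(p),
        n=n,
    )


def clinical_correlations(
    table: pd.DataFrame,
    biomarkers=None,
    clinical=("ados_css", "vabs_abc", "msel_elc"),
    by_group: bool = True,
) -> pd.DataFrame:
    """Biomarker-by-clinical-score Pearson correlations with Fisher CIs.

    Computed within diagnostic group when ``by_group`` (the clinical
    profile of a biomarker is a within-group question).  Each row
    reports r, the 95% CI, p, the n of complete pairs used, and the
    Bonferroni flag at alpha = .0167.
    """
    biomarkers = list(biomarkers) if biomarkers is not None else BIOMARKERS
    groups = table["group"].unique() if by_group else ["all"]
    rows = []
    for g in groups:
        sub = table if g == "all" else table[table["group"] == g]
        for b in biomarkers:
            for c in clinical:
                res = pearson_fisher_ci(sub[b], sub[c])
                rows.append(
                    {
                        "group": g,
                        "biomarker": b,
                        "clinical": c,
                        "r": res.r,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "p_value": res.p_value,
                        "n": res.n,
                        "significant_after_bonferroni": res.significant_after_bonferroni,
                    }
                )
    return pd.DataFrame(rows)


def screen_biomarkers(
    table: pd.DataFrame,
    biomarkers=None,
    outcome_col: str = "group",
    positive_label: str = "autism",
) -> pd.DataFrame:
    """Unadjusted and age/sex-adjusted logistic screens for each biomarker.

    Returns one row per biomarker with OR (95% CI), Wald chi-square, p,
    and AUC from the unadjusted model, plus the adjusted-model OR/CI/
    Wald/p.  Models that fail to converge or show separation are
    reported with a ``flagged`` marker.
    """
    biomarkers = list(biomarkers) if biomarkers is not None else BIOMARKERS
    d = table.copy()
    d["_y"] = (d[outcome_col] == positive_label).astype(int)
    d["_age_years"] = d["age_months"] / 12.0 if "age_months" in d else np.nan
    d["_sex_male"] = (d["sex"] == "male").astype(int) if "sex" in d else np.nan

    rows = []
    for b in biomarkers:
        row = {"biomarker": b}
        una = fit_logistic(d, "_y", b)
        eff = una.effects.get(b)
        row.update(
            n=una.n_used,
            or_=eff.odds_ratio if eff else np.nan,
            or_ci_low=eff.or_ci_low if eff else np.nan,
            or_ci_high=eff.or_ci_high if eff else np.nan,
            wald_chi2=eff.wald_chi2 if eff else np.nan,
            p_value=eff.p_value if eff else np.nan,
            auc=una.auc,
            flagged=una.flagged,
        )
        try:
            adj = fit_logistic(d, "_y", b, covariates=("_age_years", "_sex_male"))
            aeff = adj.effects.get(b)
            row.update(
                adj_or=aeff.odds_ratio if aeff else np.nan,
                adj_or_ci_low=aeff.or_ci_low if aeff else np.nan,
                adj_or_ci_high=aeff.or_ci_high if aeff else np.nan,
                adj_wald_chi2=aeff.wald_chi2 if aeff else np.nan,
                adj_p_value=aeff.p_value if aeff else np.nan,
                adj_flagged=adj.flagged,
            )
        except ValueError:
            row.update(adj_or=np.nan, adj_or_ci_low=np.nan, adj_or_ci_high=np.nan,
                       adj_wald_chi2=np.nan, adj_p_value=np.nan, adj_flagged=True)
        rows.append(row)
    out = pd.DataFrame(rows).rename(columns={"or_": "odds_ratio"})
    return out
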