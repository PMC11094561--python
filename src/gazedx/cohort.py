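"""Synthetic cohort generation for the diagnostic-accuracy pipeline.

The study population this emulates is a community-referred sample of
children aged 14-48 months evaluated for autism in primary care: 102 with
a reference-standard (expert) autism diagnosis and 44 without.  Each
child carries six candidate eye-tracking biomarkers plus auxiliary
oculomotor metrics, a primary-care practitioner (PCP) diagnosis with a
dichotomized certainty rating, and standardized clinical scores.

Group-conditional biomarker values are drawn from normal distributions
truncated to the observed ranges (sampling by rejection).  Task-level
missingness is independent across children and tasks; a missing task
blanks every metric that task produces.  PCP labels are generated from
stated sensitivity/specificity, with certainty drawn conditional on
whether the PCP call matches the child's true group — emulating the
finding that PCP accuracy covaries with diagnostic certainty.

All randomness flows from a single :func:`numpy.random.default_rng`
generator seeded from ``SimulationSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "GroupDistribution",
    "SimulationSpec",
    "BIOMARKERS",
    "AUX_METRICS",
    "CLINICAL_SCORES",
    "TASK_METRICS",
    "TABLE_DISTRIBUTIONS",
    "simulate_biomarker_table",
    "simulate_pcp_labels",
    "truncated_normal",
]

#: The six screened biomarkers (columns of the per-child biomarker table).
BIOMARKERS = [
    "nonsocial_preference_pct",
    "no_shift_gap_effect_pct",
    "resting_fixation_duration_ms",
    "plr_latency_ms",
    "plr_amplitude_pct",
    "exploration_fixation_duration_ms",
]

#: Auxiliary oculomotor/pupil metrics carried alongside the six biomarkers.
AUX_METRICS = [
    "overlap_gap_rt_ms",
    "tonic_pupil_mm",
    "saccade_amplitude_deg",
    "saccade_duration_ms",
]

CLINICAL_SCORES = ["msel_elc", "vabs_abc", "ados_css"]

#: Which metrics each eye-tracking task produces (missingness unit).
TASK_METRICS = {
    "geopref": ["nonsocial_preference_pct"],
    "gap_overlap": ["no_shift_gap_effect_pct", "overlap_gap_rt_ms"],
    "plr": ["plr_latency_ms", "plr_amplitude_pct"],
    "resting": [
        "resting_fixation_duration_ms",
        "tonic_pupil_mm",
        "saccade_amplitude_deg",
        "saccade_duration_ms",
    ],
    "exploration": ["exploration_fixation_duration_ms"],
}

TASKS = list(TASK_METRICS)


@dataclass(frozen=True)
class GroupDistribution:
    """Truncated-normal parameters for one biomarker in one group."""

    biomarker_name: str
    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"{self.biomarker_name}: sd must be >= 0")
        if not self.min < self.max:
            raise ValueError(f"{self.biomarker_name}: min must be < max")
        if not self.min <= self.mean <= self.max:
            raise ValueError(f"{self.biomarker_name}: mean outside [min, max]")


def _dist(name, mean, sd, lo, hi):
    return GroupDistribution(name, mean, sd, lo, hi)


#: Group-conditional distributions: ``{metric: {"autism": ..., "nonautism": ...}}``.
#: The six biomarkers use the published group means/SDs/ranges; the
#: auxiliary metrics (not discriminative in the study) use plausible,
#: largely overlapping values.  Clinical scores carry the cohort's group
#: statistics.
TABLE_DISTRIBUTIONS: dict[str, dict[str, GroupDistribution]] = {
    "nonsocial_preference_pct": {
        "autism": _dist("nonsocial_preference_pct", 46.20, 22.33, 3.35, 86.80),
        "nonautism": _dist("nonsocial_preference_pct", 21.50, 12.48, 0.62, 56.72),
    },
    "no_shift_gap_effect_pct": {
        "autism": _dist("no_shift_gap_effect_pct", 8.65, 13.42, -25.0, 50.0),
        "nonautism": _dist("no_shift_gap_effect_pct", 0.83, 10.45, -16.67, 40.0),
    },
    "resting_fixation_duration_ms": {
        "autism": _dist("resting_fixation_duration_ms", 527.84, 135.71, 300.0, 966.0),
        "nonautism": _dist("resting_fixation_duration_ms", 460.93, 110.47, 239.0, 686.0),
    },
    "plr_latency_ms": {
        "autism": _dist("plr_latency_ms", 268.51, 25.88, 207.0, 338.0),
        "nonautism": _dist("plr_latency_ms", 291.44, 23.62, 254.0, 353.0),
    },
    "plr_amplitude_pct": {
        "autism": _dist("plr_amplitude_pct", 32.69, 10.26, 10.17, 57.60),
        "nonautism": _dist("plr_amplitude_pct", 24.70, 8.23, 11.39, 40.55),
    },
    "exploration_fixation_duration_ms": {
        "autism": _dist("exploration_fixation_duration_ms", 344.58, 63.10, 236.0, 600.0),
        "nonautism": _dist("exploration_fixation_duration_ms", 320.80, 42.13, 232.0, 402.0),
    },
    "overlap_gap_rt_ms": {
        "autism": _dist("overlap_gap_rt_ms", 120.0, 60.0, -50.0, 350.0),
        "nonautism": _dist("overlap_gap_rt_ms", 95.0, 55.0, -50.0, 300.0),
    },
    "tonic_pupil_mm": {
        "autism": _dist("tonic_pupil_mm", 4.4, 0.5, 3.0, 6.0),
        "nonautism": _dist("tonic_pupil_mm", 4.3, 0.5, 3.0, 6.0),
    },
    "saccade_amplitude_deg": {
        "autism": _dist("saccade_amplitude_deg", 5.6, 1.2, 3.0, 10.0),
        "nonautism": _dist("saccade_amplitude_deg", 5.4, 1.2, 3.0, 10.0),
    },
    "saccade_duration_ms": {
        "autism": _dist("saccade_duration_ms", 42.0, 8.0, 20.0, 80.0),
        "nonautism": _dist("saccade_duration_ms", 40.0, 8.0, 20.0, 80.0),
    },
    "msel_elc": {
        "autism": _dist("msel_elc", 58.0, 10.0, 49.0, 101.0),
        "nonautism": _dist("msel_elc", 77.0, 16.0, 49.0, 114.0),
    },
    "vabs_abc": {
        "autism": _dist("vabs_abc", 65.0, 9.0, 30.0, 88.0),
        "nonautism": _dist("vabs_abc", 78.0, 11.0, 61.0, 109.0),
    },
    "ados_css": {
        "autism": _dist("ados_css", 9.0, 2.0, 3.0, 10.0),
        "nonautism": _dist("ados_css", 3.0, 2.0, 1.0, 10.0),
    },
}

#: Default task missingness, within the study's reported 50-94% usable range.
DEFAULT_MISSINGNESS = {
    "geopref": 0.06,
    "gap_overlap": 0.25,
    "plr": 0.40,
    "resting": 0.10,
    "exploration": 0.20,
}


@dataclass
class SimulationSpec:
    """Parameters of a synthetic cohort draw.

    Defaults reproduce the study conditions: 102 autism / 44 nonautism
    children, biomarker distributions matching the published group
    statistics, PCP sensitivity/specificity implied by the published
    decision-tree margins, and certainty more likely when the PCP call
    is correct.
    """

    n_autism: int = 102
    n_nonautism: int = 44
    distributions: dict = field(default_factory=lambda: TABLE_DISTRIBUTIONS)
    missingness_rate_per_task: dict = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS)
    )
    pcp_sensitivity: float = 71 / 102
    pcp_specificity: float = 36 / 44
    p_certain_given_correct: float = 0.75
    p_certain_given_incorrect: float = 0.40
    clinical_marker_rho: float = -0.30
    age_range_months: tuple = (14.0, 48.0)
    p_male: float = 0.71
    seed: int = 0

    def validate(self) -> None:
        if self.n_autism < 0 or self.n_nonautism < 0:
            raise ValueError("group sizes must be non-negative")
        probs = {
            "pcp_sensitivity": self.pcp_sensitivity,
            "pcp_specificity": self.pcp_specificity,
            "p_certain_given_correct": self.p_certain_given_correct,
            "p_certain_given_incorrect": self.p_certain_given_incorrect,
            "p_male": self.p_male,
            **{f"missingness[{k}]": v for k, v in self.missingness_rate_per_task.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if not -1.0 <= self.clinical_marker_rho <= 1.0:
            raise ValueError("clinical_marker_rho must lie in [-1, 1]")
        for metric, groups in self.distributions.items():
            for g in ("autism", "nonautism"):
                if g not in groups:
                    raise ValueError(f"distribution for {metric} missing group {g}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["distributions"] = {
            m: {g: asdict(gd) for g, gd in groups.items()}
            for m, groups in self.distributions.items()
        }
        return d


def truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    size: int,
) -> np.ndarray:
    """Sample a normal truncated to [lo, hi] by rejection.

    ``sd == 0`` yields the degenerate constant ``mean``.
    """
    if sd == 0:
        return np.full(size, float(mean))
    out = np.empty(size)
    n = 0
    while n < size:
        draw = rng.normal(mean, sd, size=2 * (size - n) + 16)
        keep = draw[(draw >= lo) & (draw <= hi)][: size - n]
        out[n : n + keep.size] = keep
        n += keep.size
    return out


def simulate_pcp_labels(
    groups, spec: SimulationSpec, rng: np.random.Generator | None = None
):
    """Draw PCP diagnosis and dichotomized certainty for each child.

    ``P(dx=autism | autism) = pcp_sensitivity`` and
    ``P(dx=nonautism | nonautism) = pcp_specificity``; certainty is
    Bernoulli with probability conditioned on whether the PCP call
    matches the true group.

    Returns ``(eae_dx, certainty)`` — arrays of ``{"autism","nonautism"}``
    and ``{"certain","uncertain"}`` labels.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    groups = np.asarray(groups)
    n = len(groups)
    is_autism = groups == "autism"
    u = rng.random(n)
    correct = np.where(is_autism, u < spec.pcp_sensitivity, u < spec.pcp_specificity)
    dx_autism = np.where(correct, is_autism, ~is_autism)
    eae_dx = np.where(dx_autism, "autism", "nonautism")
    p_cert = np.where(
        correct, spec.p_certain_given_correct, spec.p_certain_given_incorrect
    )
    certainty = np.where(rng.random(n) < p_cert, "certain", "uncertain")
    return eae_dx, certainty


def simulate_biomarker_table(spec: SimulationSpec | None = None) -> pd.DataFrame:
    """Generate a cohort table: one row per synthetic child.

    Columns: ``child_id``, ``group``, ``age_months``, ``sex``, the six
    biomarkers and auxiliary metrics (NaN where the producing task is
    missing), per-task ``usable_<task>`` flags, clinical scores,
    ``eae_dx`` and ``certainty``.  Deterministic for a fixed
    ``spec.seed``.

    The table's metadata (``df.attrs``) records the spec's seed.
    """
    if spec is None:
        spec = SimulationSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n = spec.n_autism + spec.n_nonautism
    groups = np.array(["autism"] * spec.n_autism + ["nonautism"] * spec.n_nonautism)

    df = pd.DataFrame(
        {
            "child_id": [f"S{i:04d}" for i in range(n)],
            "group": groups,
            "age_months": rng.uniform(*spec.age_range_months, size=n),
            "sex": np.where(rng.random(n) < spec.p_male, "male", "female"),
        }
    )

    metrics = BIOMARKERS + AUX_METRICS + CLINICAL_SCORES
    for metric in metrics:
        vals = np.empty(n)
        for g in ("autism", "nonautism"):
            gd = spec.distributions[metric][g]
            m = groups == g
            vals[m] = truncated_normal(rng, gd.mean, gd.sd, gd.min, gd.max, int(m.sum()))
        df[metric] = vals

    # Correlate MSEL/VABS with nonsocial preference within group via a
    # Gaussian-score mixture (clipped to the observed score ranges).
    rho = spec.clinical_marker_rho
    if rho != 0:
        for score in ("msel_elc", "vabs_abc"):
            for g in ("autism", "nonautism"):
                m = groups == g
                gd_m = spec.distributions["nonsocial_preference_pct"][g]
                gd_s = spec.distributions[score][g]
                if gd_m.sd == 0 or gd_s.sd == 0:
                    continue
                z = (df.loc[m, "nonsocial_preference_pct"] - gd_m.mean) / gd_m.sd
                eps = rng.standard_normal(int(m.sum()))
                s = gd_s.mean + gd_s.sd * (rho * z + np.sqrt(1 - rho**2) * eps)
                df.loc[m, score] = np.clip(s, gd_s.min, gd_s.max)

    # Task-level missingness: independent across children and tasks.
    for task in TASKS:
        rate = spec.missingness_rate_per_task.get(task, 0.0)
        usable = rng.random(n) >= rate
        df[f"usable_{task}"] = usable
        cols = [c for c in TASK_METRICS[task] if c in df.columns]
        df.loc[~usable, cols] = np.nan

    eae_dx, certainty = simulate_pcp_labels(groups, spec, rng)
    df["eae_dx"] = eae_dx
    df["certainty"] = certainty

    df.attrs["seed"] = spec.seed
    return df
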