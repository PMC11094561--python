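"""End-to-end orchestration: simulate -> extract -> screen -> composite -> cart.

A single :class:`RunConfig` (loadable from YAML) drives the whole
pipeline.  Every artifact is written with provenance metadata — the
config hash and the seed — and a fixed config+seed reproduces
byte-identical outputs.  A stage failure aborts the run with the failing
stage named.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cart as cart_mod
from . import composite as comp_mod
from . import screen as screen_mod
from .cohort import BIOMARKERS, SimulationSpec, simulate_biomarker_table
from .metrics import extract_cohort
from .streams import render_cohort_streams

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_report"]

log = logging.getLogger("gazedx")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All pipeline parameters in one place.

    ``render_streams`` selects the full path (render raw gaze streams
    and re-extract biomarkers from them) versus the cohort-table-only
    path.
    """

    seed: int = 0
    out_dir: str = "gazedx_run"
    n_autism: int = 102
    n_nonautism: int = 44
    render_streams: bool = True
    sampling_rate: float = 120.0
    noise_sd: float = 0.08
    dispersion_deg: float = 1.0
    min_fix_duration_ms: float = 100.0
    target_specificity: float = 0.95
    cart_max_splits: int = 5
    cart_min_node: int = 5
    cart_min_gain: float = 0.005
    cv_folds: int = 5
    include_published_tree: bool = True
    log_level: str = "INFO"
    sim_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_autism < 2:
            raise ValueError("n_autism must be at least 2")
        if self.n_nonautism < 5:
            raise ValueError(
                "n_nonautism must be at least 5 (cutoff derivation needs "
                "a nonautism sample)"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 < self.target_specificity <= 1:
            raise ValueError("target_specificity must lie in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def simulation_spec(self) -> SimulationSpec:
        spec = SimulationSpec(
            n_autism=self.n_autism, n_nonautism=self.n_nonautism, seed=self.seed
        )
        for k, v in self.sim_overrides.items():
            if not hasattr(spec, k):
                raise ValueError(f"unknown simulation override {k!r}")
            setattr(spec, k, v)
        spec.validate()
        return spec

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        # analysis-relevant parameters only: where outputs land and how
        # verbosely we log does not change any number
        d = {k: v for k, v in self.to_dict().items()
             if k not in ("out_dir", "log_level")}
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_json(path: Path, payload: dict, meta: dict) -> None:
    path.write_text(json.dumps({"meta": meta, **payload}, indent=2, sort_keys=True,
                               default=float) + "\n")


def _write_csv(path: Path, df: pd.DataFrame, meta: dict) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write artifacts under ``out_dir``.

    Returns a dict of stage results (tables, rules, stats, trees).
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.hash(), "seed": config.seed}
    results: dict = {"meta": meta, "config": config.to_dict()}

    stage = "simulate"
    try:
        spec = config.simulation_spec()
        table = simulate_biomarker_table(spec)
        log.info("simulated %d children", len(table))

        if config.render_streams:
            stage = "extract"
            streams, realized = render_cohort_streams(
                table, config.sampling_rate, config.noise_sd, seed=config.seed
            )
            extracted = extract_cohort(
                streams,
                dispersion_deg=config.dispersion_deg,
                min_duration_ms=config.min_fix_duration_ms,
            )
            analysis = realized.drop(columns=extracted.columns.drop("child_id")).merge(
                extracted, on="child_id"
            )
            results["ground_truth_table"] = realized
        else:
            analysis = table
        results["cohort_table"] = analysis
        _write_csv(out / "cohort.csv", analysis, meta)

        stage = "screen"
        screen_df = screen_mod.screen_biomarkers(analysis)
        corr_df = screen_mod.clinical_correlations(analysis)
        results["screen"] = screen_df
        results["correlations"] = corr_df
        _write_csv(out / "screen.csv", screen_df, meta)
        _write_csv(out / "correlations.csv", corr_df, meta)

        stage = "composite"
        rules = comp_mod.derive_all_cutoffs(
            analysis, target_specificity=config.target_specificity
        )
        composed = comp_mod.compose_table(analysis, rules)
        ref_pos = (analysis["group"] == "autism").to_numpy()
        confusion = comp_mod.confusion_from_labels(
            composed["composite_positive"].to_numpy().astype(bool), ref_pos
        )
        stats = comp_mod.accuracy_stats(confusion)
        results["cutoffs"] = rules
        results["composite_table"] = composed
        results["composite_confusion"] = confusion
        results["composite_stats"] = stats
        _write_csv(out / "composite.csv", composed, meta)
        _write_json(
            out / "cutoffs.json",
            {
                "rules": {
                    k: {
                        "direction": r.direction,
                        "threshold": r.threshold,
                        "achieved_specificity": r.achieved_specificity,
                        "degenerate": r.degenerate,
                    }
                    for k, r in rules.items()
                }
            },
            meta,
        )
        _write_json(
            out / "composite_accuracy.json",
            {
                "confusion": {"tp": confusion.tp, "fp": confusion.fp,
                              "fn": confusion.fn, "tn": confusion.tn},
                "stats": stats.to_dict(),
            },
            meta,
        )

        stage = "cart"
        features = pd.DataFrame(
            {
                "composite": composed["composite_positive"].to_numpy(),
                "frequency": composed["biomarker_frequency"].to_numpy(),
                "eae_dx": (analysis["eae_dx"] == "autism").astype(int).to_numpy(),
                "certainty": (analysis["certainty"] == "certain").astype(int).to_numpy(),
            }
        )
        y = ref_pos.astype(int)
        tree = cart_mod.fit_cart(
            features, y,
            max_splits=config.cart_max_splits,
            min_node=config.cart_min_node,
            min_gain=config.cart_min_gain,
        )
        policy = cart_mod.majority_policy(tree)
        tree_stats, referred = cart_mod.evaluate_decided(tree, policy, features, y)
        cv = cart_mod.cross_validate(
            features, y, k=config.cv_folds, seed=config.seed,
            max_splits=config.cart_max_splits,
            min_node=config.cart_min_node,
            min_gain=config.cart_min_gain,
        )
        results["tree"] = tree
        results["tree_policy"] = policy
        results["tree_stats"] = tree_stats
        results["tree_referred"] = referred
        results["cv"] = cv
        payload = {
            "tree": cart_mod.tree_to_dict(tree, policy),
            "stats": tree_stats.to_dict(),
            "referred": referred,
            "cv": {
                "train_auc": cv.train_auc,
                "valid_auc": cv.valid_auc,
                "mean_valid_auc": cv.mean_valid_auc,
                "modal_structure_count": cv.modal_structure_count,
            },
        }
        if config.include_published_tree:
            pub = cart_mod.published_tree()
            pub_stats, pub_ref = cart_mod.evaluate_decided(
                pub, cart_mod.PUBLISHED_POLICY
            )
            results["published_tree"] = pub
            results["published_stats"] = pub_stats
            results["published_referred"] = pub_ref
            payload["published_tree"] = {
                "tree": cart_mod.tree_to_dict(pub, cart_mod.PUBLISHED_POLICY),
                "stats": pub_stats.to_dict(),
                "referred": pub_ref,
            }
        _write_json(out / "cart.json", payload, meta)
    except Exception as exc:
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = make_report(results)
    (out / "report.txt").write_text(report)
    results["report"] = report
    return results


def _fmt_pct(x):
    return f"{100 * x:.1f}%" if np.isfinite(x) else "missing"


def make_report(results: dict) -> str:
    """Human-readable multi-section summary of available stage outputs."""
    lines = []
    meta = results.get("meta", {})
    lines.append(f"gazedx run  (config {meta.get('config_hash', '?')}, "
                 f"seed {meta.get('seed', '?')})")
    lines.append("=" * 60)

    screen = results.get("screen")
    if screen is not None:
        lines.append("\n[1] Biomarker screening (logistic regression)")
        for _, r in screen.iterrows():
            lines.append(
                f"  {r['biomarker']:<34} OR {r['odds_ratio']:.3f} "
                f"({r['or_ci_low']:.3f}-{r['or_ci_high']:.3f})  "
                f"Wald {r['wald_chi2']:.1f}  p {r['p_value']:.3g}  AUC {r['auc']:.2f}"
            )
    else:
        lines.append("\n[1] Biomarker screening: absent")

    rules = results.get("cutoffs")
    if rules is not None:
        lines.append("\n[2] 95%-specificity cutoffs")
        for name, rule in rules.items():
            lines.append(
                f"  {name:<34} {rule.direction:<16} thr {rule.threshold:.2f} "
                f"(achieved spec {rule.achieved_specificity:.3f})"
            )
    else:
        lines.append("\n[2] Cutoffs: absent")

    stats = results.get("composite_stats")
    if stats is not None:
        conf = results["composite_confusion"]
        lines.append("\n[3] Composite biomarker accuracy")
        lines.append(
            f"  TP {conf.tp}  FP {conf.fp}  FN {conf.fn}  TN {conf.tn}"
        )
        lines.append(
            f"  sensitivity {_fmt_pct(stats.sensitivity)}  "
            f"specificity {_fmt_pct(stats.specificity)}  "
            f"PPV {_fmt_pct(stats.ppv)}  NPV {_fmt_pct(stats.npv)}  "
            f"kappa {stats.kappa:.2f}"
        )
    else:
        lines.append("\n[3] Composite accuracy: absent")

    tree = results.get("tree")
    if tree is not None:
        lines.append("\n[4] Decision tree (fitted)")
        lines.append(cart_mod.render_tree_text(tree, results.get("tree_policy")).rstrip())
        ts = results.get("tree_stats")
        if ts is not None and np.isfinite(ts.sensitivity):
            lines.append(
                f"  decided n {ts.n}  referred {results.get('tree_referred', 0)}  "
                f"sens {_fmt_pct(ts.sensitivity)}  spec {_fmt_pct(ts.specificity)}"
            )
        cv = results.get("cv")
        if cv is not None:
            lines.append(
                f"  5-fold CV: mean train AUC {cv.mean_train_auc:.2f}, "
                f"mean valid AUC {cv.mean_valid_auc:.2f}, "
                f"modal structure in {cv.modal_structure_count}/{len(cv.fold_structures)} folds"
            )
    else:
        lines.append("\n[4] Decision tree: absent")

    pub = results.get("published_stats")
    if pub is not None:
        lines.append("\n[5] Published decision tree, worked example (stored counts)")
        lines.append(cart_mod.render_tree_text(
            results["published_tree"], cart_mod.PUBLISHED_POLICY).rstrip())
        lines.append(
            f"  decided n {pub.n}  referred {results.get('published_referred', 0)}  "
            f"sens {_fmt_pct(pub.sensitivity)}  spec {_fmt_pct(pub.specificity)}  "
            f"PPV {_fmt_pct(pub.ppv)}  NPV {_fmt_pct(pub.npv)}  kappa {pub.kappa:.2f}"
        )
    return "\n".join(lines) + "\n"
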