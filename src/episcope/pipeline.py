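"""End-to-end orchestration: simulate/load -> filter -> select -> classify
-> evaluate, with a run manifest for exact reproduction.

Every stage draws its seed deterministically from the global seed, reads
only prior-stage artifacts, and writes plain-text tables with fixed float
formatting, so two runs with the same configuration and seed produce
byte-identical result tables. The manifest records package version,
parameters, derived seeds, input hashes and the row-count ledger across
the filtering stages (total -> annotated -> stable -> selected).
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

from . import __version__
from .classifier import (
    ClassifierReport,
    ForestConfig,
    episave_augment,
    loocv_evaluate,
    self_test,
    train_forest,
    transfer_test,
)
from .filters import annotation_filter, stability_filter
from .io import (
    read_beta_matrix,
    read_manifest,
    read_sample_sheet,
    drop_missing_probes,
    write_result_table,
)
from .lasso import PAPER_ALPHA_GRID, build_feature_table, fit_lasso_path
from .simulate import SynthConfig, config_from_dict, config_to_dict, generate, write_cohort
from .survival import clinical_score_benchmark, compare_groups, km_curve, logrank_test, roc_auc

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "stage_seed",
    "evaluate_predictions",
    "write_classifier_report",
]


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed (kept below 2^31)."""
    return (int(global_seed) * 1_000_003 + 7919 * stage_index) % (2**31)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``synth`` (a SynthConfig) or ``inputs`` (paths to the
    three beta matrices, manifest and sample sheet) must be provided.
    """

    seed: int = 0
    synth: SynthConfig | None = None
    inputs: dict | None = None  # keys t0, t2, tr, manifest, sheet
    wilcoxon: str = "auto"  # or "approx"
    p_threshold: float = 0.8
    alphas: tuple = PAPER_ALPHA_GRID
    table_alphas: tuple | None = None  # default: path alphas > 0.01
    classify_alphas: tuple = (0.1,)
    standardize: bool = True
    cv_folds: int = 0
    episave: bool = True
    forest: ForestConfig = field(default_factory=ForestConfig)

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.inputs is None):
            raise ValueError("exactly one of synth/inputs must be given")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "synth" in raw and raw["synth"] is not None:
            raw["synth"] = config_from_dict(raw["synth"])
        if "forest" in raw and raw["forest"] is not None:
            raw["forest"] = ForestConfig(**raw["forest"])
        for key in ("alphas", "table_alphas", "classify_alphas"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synth is not None:
            d["synth"] = config_to_dict(self.synth)
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _metrics_row(label: str, metrics: dict) -> dict:
    return {"row": label} | {k: metrics[k] for k in ("accuracy", "precision", "recall", "f1")}


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages; returns in-memory results plus the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "episcope",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stage_seeds": {},
        "counts": {},
        "input_hashes": {},
    }
    meta = {"episcope_version": __version__, "seed": config.seed}

    # ---- stage 0: simulate or load -------------------------------------
    try:
        if config.synth is not None:
            synth = SynthConfig(**{**config_to_dict(config.synth)})
            synth.seed = stage_seed(config.seed, 0)
            manifest["stage_seeds"]["simulate"] = synth.seed
            sim = generate(synth)
            paths = write_cohort(out / "data", sim)
            t0, t2, tr = sim.t0, sim.t2, sim.tr
            probe_manifest, cohort = sim.manifest, sim.cohort
            manifest["input_hashes"] = {k: _sha256(p) for k, p in paths.items()}
            truth = sim.truth
        else:
            p = config.inputs
            t0 = read_beta_matrix(p["t0"], "t0")
            t2 = read_beta_matrix(p["t2"], "t2")
            tr = read_beta_matrix(p["tr"], "tr")
            probe_manifest = read_manifest(p["manifest"])
            cohort = read_sample_sheet(p["sheet"])
            manifest["input_hashes"] = {k: _sha256(v) for k, v in p.items()}
            truth = None
        manifest["counts"]["probes_total"] = len(t0.probe_ids)
        manifest["counts"]["patients"] = len(cohort.patient_ids)
        logger.info("stage load: %d probes, %d patients", len(t0.probe_ids),
                    len(cohort.patient_ids))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'load/simulate' failed: {exc}") from exc

    # ---- stage 1: filtering --------------------------------------------
    try:
        t0, t2, tr = drop_missing_probes(t0, t2, tr)
        manifest["counts"]["probes_complete"] = len(t0.probe_ids)
        annotated = annotation_filter(t0, probe_manifest)
        if not annotated:
            raise ValueError("no annotated probes survive the annotation filter")
        stable = stability_filter(
            t0, tr, cohort, annotated, config.p_threshold, wilcoxon_method=config.wilcoxon
        )
        stable.to_tsv(out / "stable_probes.tsv", meta=meta)
        manifest["counts"]["probes_annotated"] = stable.n_annotated
        manifest["counts"]["probes_stable"] = stable.n_retained
        logger.info("stage filter: %d -> %d annotated -> %d stable",
                    stable.n_input, stable.n_annotated, stable.n_retained)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'filter' failed: {exc}") from exc

    # ---- stage 2: LASSO feature selection ------------------------------
    try:
        stable_ids = stable.retained_ids
        if not stable_ids:
            raise ValueError("no stable probes retained; cannot select features")
        patients = cohort.patient_ids
        X0 = t0.subset_probes(stable_ids).values[patients].to_numpy().T
        y = cohort.outcome_vector(patients)
        lasso_seed = stage_seed(config.seed, 2)
        manifest["stage_seeds"]["select"] = lasso_seed
        path = fit_lasso_path(
            X0, y, stable_ids, config.alphas,
            standardize=config.standardize, cv_folds=config.cv_folds, seed=lasso_seed,
        )
        table = build_feature_table(path, X0, y, probe_manifest, alphas=config.table_alphas)
        write_result_table(out / "lasso_path.tsv", path.summary(), meta=meta)
        write_result_table(out / "feature_table.tsv", table, meta=meta)
        manifest["counts"]["features_per_alpha"] = {
            f"{a:g}": path.n_features(a) for a in path.alphas
        }
        logger.info("stage select: features per alpha %s",
                    manifest["counts"]["features_per_alpha"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'select' failed: {exc}") from exc

    # ---- stage 3: classification ---------------------------------------
    results: dict = {"lasso_path": path, "feature_table": table, "stable": stable,
                     "cohort": cohort, "truth": truth, "reports": {}}
    try:
        rf_seed = stage_seed(config.seed, 3)
        manifest["stage_seeds"]["classify"] = rf_seed
        for a in config.classify_alphas:
            selected = sorted(path.selected(a))
            if not selected:
                raise ValueError(f"alpha {a} selected no features")
            Xtr = t0.subset_probes(selected).values[patients].to_numpy().T
            Xte = t2.subset_probes(selected).values[patients].to_numpy().T
            variants = {"methylation": (Xtr, Xte)}
            if config.episave:
                variants["episave"] = (
                    episave_augment(Xtr, cohort, patients),
                    episave_augment(Xte, cohort, patients),
                )
            for variant, (Xa, Xb) in variants.items():
                fc = ForestConfig(**{**asdict(config.forest), "seed": rf_seed})
                report = loocv_evaluate(Xa, y, fc, sample_ids=patients)
                forest = train_forest(Xa, y, fc)
                report.train_self_metrics = self_test(forest, Xa, y)
                t_rep = transfer_test(forest, Xb, y, sample_ids=patients)
                report.test_metrics = t_rep.test_metrics
                report.test_probabilities = t_rep.test_probabilities
                report.feature_ids = selected + (["save_score"] if variant == "episave" else [])
                results["reports"][(a, variant)] = report
                write_classifier_report(out, a, variant, report, meta)
        logger.info("stage classify: %d report(s)", len(results["reports"]))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'classify' failed: {exc}") from exc

    # ---- stage 4: evaluation -------------------------------------------
    try:
        votes_by_model = {
            key: rep.test_probabilities for key, rep in results["reports"].items()
        }
        results.update(evaluate_predictions(votes_by_model, cohort, out / "eval", meta=meta))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'evaluate' failed: {exc}") from exc

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    results["manifest"] = manifest
    return results


def write_classifier_report(out: Path, alpha: float, variant: str,
                             report: ClassifierReport, meta: dict) -> None:
    d = out / f"report_alpha_{alpha:g}_{variant}"
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    summ = report.loocv_summary
    for metric in ("accuracy", "precision", "recall", "f1"):
        rows.append({"row": f"loocv_{metric}",
                     "mean": summ.loc[metric, "mean"], "sd": summ.loc[metric, "sd"]})
    table = pd.DataFrame(rows)
    extra = pd.DataFrame(
        [_metrics_row("train_self", report.train_self_metrics),
         _metrics_row("test_t2", report.test_metrics)]
    )
    local_meta = meta | {"alpha": f"{alpha:g}", "variant": variant,
                         "features": ",".join(report.feature_ids)}
    write_result_table(d / "classifier_report.tsv", table, meta=local_meta)
    write_result_table(d / "pooled_metrics.tsv", extra, meta=local_meta)
    probs = report.test_probabilities.rename_axis("patient_id").reset_index()
    write_result_table(d / "probabilities.tsv", probs, meta=local_meta)


def evaluate_predictions(votes_by_model, cohort, eval_dir, *, meta=None) -> dict:
    """Survival + discrimination evaluation of per-model transfer votes.

    ``votes_by_model`` maps (alpha, variant) to a per-patient vote-fraction
    Series; writes roc/km/logrank/table1/clinical_scores tables under
    ``eval_dir`` and returns the in-memory result objects.
    """
    eval_dir = Path(eval_dir)
    eval_dir.mkdir(parents=True, exist_ok=True)
    meta = meta or {}
    results: dict = {"roc": {}, "logrank": {}}
    roc_rows, km_rows, lr_rows = [], [], []
    for (a, variant), votes in votes_by_model.items():
        patients = list(votes.index)
        y = cohort.outcome_vector(patients)
        roc = roc_auc(votes.to_numpy(), y)
        results["roc"][(a, variant)] = roc
        roc_rows.append(
            {"alpha": a, "variant": variant, "auc": roc.auc, "p_value": roc.p_value,
             "n_pos": roc.n_pos, "n_neg": roc.n_neg}
        )
        pred_ns = votes.to_numpy() >= 0.5
        times = cohort.data.loc[patients, "time_to_event"].to_numpy(dtype=float)
        events = cohort.data.loc[patients, "event_observed"].to_numpy(dtype=bool)
        for grp, sel in (("pred_survivor", ~pred_ns), ("pred_non_survivor", pred_ns)):
            if sel.any():
                km = km_curve(times[sel], events[sel])
                for t, ar, ev, ce, s in zip(km.times, km.at_risk, km.events,
                                            km.censored, km.survival):
                    km_rows.append({"alpha": a, "variant": variant, "group": grp,
                                    "time": t, "at_risk": ar, "events": ev,
                                    "censored": ce, "survival": s})
        if pred_ns.any() and (~pred_ns).any():
            lr = logrank_test(times[~pred_ns], events[~pred_ns],
                              times[pred_ns], events[pred_ns])
            results["logrank"][(a, variant)] = lr
            lr_rows.append({"alpha": a, "variant": variant,
                            "chi_square": lr.chi_square, "p_value": lr.p_value})
        else:
            lr_rows.append({"alpha": a, "variant": variant,
                            "chi_square": float("nan"), "p_value": float("nan")})
    write_result_table(eval_dir / "roc.tsv", pd.DataFrame(roc_rows), meta=meta)
    write_result_table(eval_dir / "km.tsv", pd.DataFrame(km_rows), meta=meta)
    write_result_table(eval_dir / "logrank.tsv", pd.DataFrame(lr_rows), meta=meta)

    table1 = compare_groups(cohort, "outcome")
    write_result_table(eval_dir / "table1.tsv", table1, meta=meta)
    results["table1"] = table1
    scores = clinical_score_benchmark(cohort, "early_outcome")
    score_rows = [
        {"score": s, "endpoint": "early_outcome", "auc": r.auc, "p_value": r.p_value,
         "direction": r.direction}
        for s, r in scores.items()
    ]
    scores_ih = clinical_score_benchmark(cohort, "outcome")
    score_rows += [
        {"score": s, "endpoint": "outcome", "auc": r.auc, "p_value": r.p_value,
         "direction": r.direction}
        for s, r in scores_ih.items()
    ]
    write_result_table(eval_dir / "clinical_scores.tsv", pd.DataFrame(score_rows), meta=meta)
    results["clinical_scores"] = {"early_outcome": scores, "outcome": scores_ih}
    return results
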