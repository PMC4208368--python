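"""Pipeline stages: simulate -> extract -> reduce -> classify -> evaluate.

Each stage reads the previous stage's serialized artifact and writes its own,
so the chained single-stage runs and ``run_all`` produce identical results
for the same config. :func:`run_in_memory` performs the same computation
without touching disk (used by the analysis drivers and the acceptance
script).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import factors, io, logistic
from .config import PipelineConfig
from .features import assemble_feature_table, extract_subject
from .registry import default_registry, load_registry, registry_ids
from .synthetic import iter_cohort, sample_cohort_features

log = logging.getLogger("fallrisk")

__all__ = [
    "stage_simulate",
    "stage_extract",
    "stage_reduce",
    "stage_classify",
    "stage_evaluate",
    "run_all",
    "run_in_memory",
]


def _hl_groups(n: int) -> int:
    """Deciles of risk when the cohort allows; fewer bins on tiny cohorts."""
    return min(10, max(3, n // 3))


def _registry(cfg: PipelineConfig):
    if cfg.registry_path:
        return load_registry(cfg.registry_path)
    return default_registry()


def stage_simulate(cfg: PipelineConfig, outdir) -> Path:
    """Generate the synthetic cohort; write trials, ground truth and the
    manifest under ``outdir/trials``."""
    outdir = Path(outdir)
    tdir = outdir / "trials"
    tdir.mkdir(parents=True, exist_ok=True)
    anthros = []
    for rec, anthro in iter_cohort(cfg.cohort):
        sdir = tdir / rec.params.subject_id
        sdir.mkdir(exist_ok=True)
        for trial in rec.trials:
            io.write_trial(trial, sdir / f"{trial.trial_id}.csv")
        io.write_json(rec.ground_truth, sdir / "ground_truth.json")
        anthros.append((rec.params, anthro))
        log.info("simulated %s (%s): %d trials", rec.params.subject_id,
                 rec.params.group, len(rec.trials))
    from .synthetic import build_manifest

    io.write_manifest(build_manifest(anthros), outdir / "manifest.csv")
    return outdir


def stage_extract(cfg: PipelineConfig, indir, out_csv) -> Path:
    """Extract the measure battery from the simulated trials."""
    indir = Path(indir)
    manifest = io.read_manifest(indir / "manifest.csv")
    measures = {}
    for sid in manifest.index:
        sdir = indir / "trials" / sid
        if not sdir.is_dir():
            raise FileNotFoundError(f"missing trials for subject {sid}: {sdir}")
        trials = [
            io.read_trial(p) for p in sorted(sdir.glob("*.csv"))
        ]
        measures[sid] = extract_subject(trials, cfg.extraction)
        log.info("extracted %s: %d measures", sid, len(measures[sid]))
    table = assemble_feature_table(measures, _registry(cfg))
    io.write_feature_table(table, out_csv)
    return Path(out_csv)


def stage_reduce(cfg: PipelineConfig, features_csv, outdir) -> Path:
    """Standardize and iteratively factor-reduce the feature table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = io.read_feature_table(features_csv, _registry(cfg))
    z = factors.standardize(table)
    sol = factors.iterative_reduce(
        z,
        msa_threshold=cfg.msa_threshold,
        loading_threshold=cfg.loading_threshold,
        kaiser=cfg.kaiser,
    )
    scores = factors.component_scores(sol, z)
    io.write_json(sol.to_dict(), outdir / "factor_solution.json")
    scores.index.name = "subject_id"
    scores.to_csv(outdir / "component_scores.csv", float_format="%.12g")
    for entry in sol.iteration_log:
        log.info(
            "iteration %d: %d measures, %d components, dropped %d (MSA) + %d (complex)",
            entry["iteration"], entry["n_measures"], entry["n_components"],
            len(entry["dropped_msa"]), len(entry["dropped_complex"]),
        )
    return outdir


def stage_classify(cfg: PipelineConfig, reduce_dir, manifest_csv, outdir) -> Path:
    """Fit the logistic models on the component scores."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reduce_dir = Path(reduce_dir)
    scores = pd.read_csv(reduce_dir / "component_scores.csv", index_col="subject_id")
    scores.index = scores.index.astype(str)
    manifest = io.read_manifest(manifest_csv)
    sol = io.read_json(reduce_dir / "factor_solution.json")
    labels = manifest.loc[scores.index, "fall_label"]
    full = logistic.fit_logistic(scores, labels)
    full.labels = dict(zip(sol["components"], sol["component_labels"]))
    reduced = logistic.select_components(full, scores, labels, alpha=cfg.selection_alpha)
    model = reduced if cfg.model_choice == "reduced" else full
    prob, cls = logistic.predict(model, scores, threshold=cfg.classification_threshold)
    io.write_json(
        {"full": full.to_dict(), "reduced": reduced.to_dict(),
         "model_choice": cfg.model_choice},
        outdir / "logistic_models.json",
    )
    pred = pd.DataFrame(
        {"probability": prob, "predicted": cls, "observed": labels}
    )
    pred.index.name = "subject_id"
    pred.to_csv(outdir / "predictions.csv", float_format="%.12g")
    return outdir


def stage_evaluate(cfg: PipelineConfig, classify_dir, reduce_dir, manifest_csv, outdir) -> Path:
    """Confusion matrix, metrics, diagnostics and the assembled run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    classify_dir, reduce_dir = Path(classify_dir), Path(reduce_dir)
    pred = pd.read_csv(classify_dir / "predictions.csv", index_col="subject_id")
    scores = pd.read_csv(reduce_dir / "component_scores.csv", index_col="subject_id")
    scores.index = scores.index.astype(str)
    pred.index = pred.index.astype(str)
    manifest = io.read_manifest(manifest_csv)
    models = io.read_json(classify_dir / "logistic_models.json")
    sol = io.read_json(reduce_dir / "factor_solution.json")

    cm = ev.confusion_matrix(pred["predicted"], pred["observed"])
    model_key = models["model_choice"]
    chosen = models[model_key]
    hl = logistic.hosmer_lemeshow(
        pred["probability"].to_numpy(),
        pred["observed"].to_numpy(),
        groups=_hl_groups(len(pred)),
    )
    diagnostics = {
        "nagelkerke_r2": chosen["nagelkerke_r2"],
        "hosmer_lemeshow": hl,
        "model_evaluated": model_key,
    }
    groups = manifest.loc[scores.index, "group"]
    comparison = ev.group_comparison(scores, groups)
    report = ev.build_report(
        seed=cfg.seed,
        config=cfg.to_dict(),
        registry=registry_ids(_registry(cfg)),
        factor_solution=sol,
        full_model=models["full"],
        reduced_model=models["reduced"],
        diagnostics=diagnostics,
        confusion=cm,
        group_scores=comparison,
    )
    io.write_json(report, outdir / "report.json")
    _write_text_report(report, outdir / "report.txt")
    return outdir


def _fmt_table(rows: list[list[str]]) -> str:
    widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
    return "\n".join(
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)) for row in rows
    )


def _write_text_report(report: dict, path) -> None:
    s = report["sections"]
    lines = [f"fallrisk run report (seed={report['seed']})", ""]
    sol = s.get("factor_solution") or {}
    if "components" in sol:
        lines.append(
            f"factor solution: {len(sol['components'])} components over "
            f"{len(sol['measures'])} retained measures "
            f"({len(sol['iteration_log'])} iterations, KMO={sol['kmo']:.3f})"
        )
        rows = [["component", "label", "variance %"]]
        for c, lab, v in zip(
            sol["components"], sol["component_labels"], sol["variance_explained_pct"]
        ):
            rows.append([c, lab, f"{v:.1f}"])
        lines += [_fmt_table(rows), ""]
    for key in ("logistic_full", "logistic_reduced"):
        m = s.get(key) or {}
        if "coefficients" in m:
            lines.append(f"{key} (n={m['n']}, Nagelkerke R2={m['nagelkerke_r2']:.3f})")
            rows = [["predictor", "label", "beta", "s.e.", "Wald", "p", "exp(beta)"]]
            for name, c in m["coefficients"].items():
                rows.append(
                    [
                        name,
                        m.get("labels", {}).get(name, ""),
                        f"{c['beta']:.2f}",
                        f"{c['se']:.2f}",
                        f"{c['wald']:.2f}",
                        f"{c['p']:.3f}",
                        f"{c['exp_beta']:.2f}",
                    ]
                )
            lines += [_fmt_table(rows), ""]
    cmd = s.get("confusion_matrix") or {}
    if "tp" in cmd:
        met = s["classification_metrics"]
        lines.append("classification (in-sample):")
        lines.append(
            f"  TP={cmd['tp']} FN={cmd['fn']} FP={cmd['fp']} TN={cmd['tn']}"
        )
        lines.append(
            "  sensitivity {sensitivity}%  specificity {specificity}%  "
            "PPV {ppv}%  NPV {npv}%".format(**met)
        )
    diag = s.get("diagnostics") or {}
    if "hosmer_lemeshow" in diag:
        hl = diag["hosmer_lemeshow"]
        lines.append(
            f"  Hosmer-Lemeshow chi2={hl['chi2']:.2f} (df={hl['df']}), p={hl['p']:.2f}"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def run_all(cfg: PipelineConfig, outdir) -> Path:
    """Full chain with on-disk artifacts between stages."""
    outdir = Path(outdir)
    stage_simulate(cfg, outdir)
    stage_extract(cfg, outdir, outdir / "features.csv")
    stage_reduce(cfg, outdir / "features.csv", outdir / "reduce")
    stage_classify(cfg, outdir / "reduce", outdir / "manifest.csv", outdir / "classify")
    stage_evaluate(
        cfg, outdir / "classify", outdir / "reduce", outdir / "manifest.csv", outdir
    )
    return outdir


def run_in_memory(cfg: PipelineConfig, fast: bool = False) -> dict:
    """Run the full analysis without disk artifacts; returns the report dict
    plus the in-memory intermediates.

    ``fast=True`` uses the feature-level sampling path (identical cycle-level
    draws, no marker synthesis / event detection) — used for the many-seed
    Monte-Carlo checks.
    """
    if fast:
        table, manifest = sample_cohort_features(cfg.cohort, cfg.extraction)
    else:
        measures = {}
        anthros = []
        for rec, anthro in iter_cohort(cfg.cohort):
            measures[rec.params.subject_id] = extract_subject(rec.trials, cfg.extraction)
            anthros.append((rec.params, anthro))
        from .synthetic import build_manifest

        table = assemble_feature_table(measures, _registry(cfg))
        manifest = build_manifest(anthros)

    z = factors.standardize(table)
    sol = factors.iterative_reduce(
        z,
        msa_threshold=cfg.msa_threshold,
        loading_threshold=cfg.loading_threshold,
        kaiser=cfg.kaiser,
    )
    scores = factors.component_scores(sol, z)
    labels = manifest.loc[scores.index, "fall_label"]
    full = logistic.fit_logistic(scores, labels)
    full.labels = dict(zip(scores.columns, sol.component_labels))
    reduced = logistic.select_components(full, scores, labels, alpha=cfg.selection_alpha)
    model = reduced if cfg.model_choice == "reduced" else full
    prob, cls = logistic.predict(model, scores, threshold=cfg.classification_threshold)
    cm = ev.confusion_matrix(cls, labels)
    hl = logistic.hosmer_lemeshow(
        prob.to_numpy(), labels.to_numpy(), groups=_hl_groups(len(prob))
    )
    groups = manifest.loc[scores.index, "group"]
    report = ev.build_report(
        seed=cfg.seed,
        config=cfg.to_dict(),
        registry=registry_ids(_registry(cfg)),
        factor_solution=sol.to_dict(),
        full_model=full.to_dict(),
        reduced_model=reduced.to_dict(),
        diagnostics={
            "nagelkerke_r2": logistic.nagelkerke_r2(model),
            "hosmer_lemeshow": hl,
            "model_evaluated": cfg.model_choice,
        },
        confusion=cm,
        group_scores=ev.group_comparison(scores, groups),
    )
    return {
        "report": report,
        "table": table,
        "manifest": manifest,
        "solution": sol,
        "scores": scores,
        "full_model": full,
        "reduced_model": reduced,
        "confusion": cm,
        "probabilities": prob,
    }
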