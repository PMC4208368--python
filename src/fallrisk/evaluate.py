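"""Classification surface and group-level comparisons.

Faller is the positive class throughout. Percentages are rounded half away
from zero, and only at the presentation layer — metric identities hold
exactly on the integer counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "classification_metrics",
    "group_comparison",
    "build_report",
    "round_half_away",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name, v in (("tp", self.tp), ("fn", self.fn), ("fp", self.fp), ("tn", self.tn)):
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion_matrix(predicted, observed) -> ConfusionMatrix:
    """Counts of predicted vs observed fall status (faller = positive)."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must be aligned, equal-length")
    for arr, name in ((pred, "predicted"), (obs, "observed")):
        if not set(np.unique(arr)) <= {0.0, 1.0}:
            raise ValueError(f"{name} labels outside {{0, 1}}")
    return ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (obs == 1))),
        fn=int(np.sum((pred == 0) & (obs == 1))),
        fp=int(np.sum((pred == 1) & (obs == 0))),
        tn=int(np.sum((pred == 0) & (obs == 0))),
    )


def round_half_away(x: float) -> int:
    """Round half away from zero (so 73.68 -> 74, 76.19 -> 76, 0.5 -> 1)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def classification_metrics(cm: ConfusionMatrix, rounded: bool = True) -> dict:
    """Sensitivity, specificity, PPV and NPV in percent.

    Zero-denominator metrics come back as NaN (flagged undefined).
    """

    def _pct(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    raw = {
        "sensitivity": _pct(cm.tp, cm.tp + cm.fn),
        "specificity": _pct(cm.tn, cm.tn + cm.fp),
        "ppv": _pct(cm.tp, cm.tp + cm.fp),
        "npv": _pct(cm.tn, cm.tn + cm.fn),
    }
    if not rounded:
        return raw
    return {
        k: (round_half_away(v) if not math.isnan(v) else float("nan"))
        for k, v in raw.items()
    }


def group_comparison(scores: pd.DataFrame, groups: pd.Series) -> dict:
    """Per-component score summaries for F / NF' / FTF plus Welch two-sample
    tests of F vs NF' (the first-time-faller subset is too small and uneven
    for testing and is reported descriptively only)."""
    groups = groups.reindex(scores.index)
    out: dict = {"components": {}, "ftf_descriptive_only": True}
    names = {"faller": "F", "nonfaller": "NF'", "ftf": "FTF"}
    for comp in scores.columns:
        entry: dict = {"groups": {}}
        for g, short in names.items():
            vals = scores.loc[groups == g, comp]
            if len(vals) == 0:
                warnings.warn(f"group {g} empty; omitted from comparison")
                continue
            entry["groups"][short] = {
                "n": int(len(vals)),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            }
        f = scores.loc[groups == "faller", comp]
        nf = scores.loc[groups == "nonfaller", comp]
        if len(f) > 1 and len(nf) > 1:
            t, p = spstats.ttest_ind(f, nf, equal_var=False)
            entry["welch_f_vs_nf"] = {"t": float(t), "p": float(p)}
        if all(k in entry["groups"] for k in ("F", "NF'", "FTF")):
            mf = entry["groups"]["F"]["mean"]
            mn = entry["groups"]["NF'"]["mean"]
            mt = entry["groups"]["FTF"]["mean"]
            entry["ftf_between"] = bool(min(mf, mn) <= mt <= max(mf, mn))
        out["components"][comp] = entry
    return out


def build_report(
    *,
    seed: int,
    config: dict,
    registry: list[str],
    factor_solution: dict | None = None,
    full_model: dict | None = None,
    reduced_model: dict | None = None,
    diagnostics: dict | None = None,
    confusion: ConfusionMatrix | None = None,
    metrics: dict | None = None,
    group_scores: dict | None = None,
) -> dict:
    """Assemble the machine-readable run report; missing stages leave
    explicit gaps."""
    report = {
        "seed": seed,
        "config": config,
        "registry": registry,
        "classification_design": "in-sample (retrospective)",
        "sections": {},
    }
    sections = report["sections"]
    for name, payload in (
        ("factor_solution", factor_solution),
        ("logistic_full", full_model),
        ("logistic_reduced", reduced_model),
        ("diagnostics", diagnostics),
        ("group_scores", group_scores),
    ):
        sections[name] = payload if payload is not None else {"status": "absent"}
    if confusion is not None:
        sections["confusion_matrix"] = {
            "tp": confusion.tp,
            "fn": confusion.fn,
            "fp": confusion.fp,
            "tn": confusion.tn,
        }
        sections["classification_metrics"] = metrics or classification_metrics(confusion)
    else:
        sections["confusion_matrix"] = {"status": "absent"}
        sections["classification_metrics"] = {"status": "absent"}
    return report
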