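#!/usr/bin/env python
"""Classification surface and group-level component-score comparison.

Builds the confusion matrix (faller = positive), sensitivity/specificity/
PPV/NPV, Hosmer-Lemeshow goodness of fit, and the F vs NF' Welch tests with
the first-time-faller subset reported descriptively. Assembles the full run
report under results/.
"""

import argparse
import logging
import shutil
import warnings
from pathlib import Path

from fallrisk.config import PipelineConfig
from fallrisk.pipeline import stage_evaluate
from fallrisk import io

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    logging.basicConfig(level=logging.WARNING)

    cfg = PipelineConfig(seed=args.seed)
    run_dir = ROOT / "scratch" / f"run_seed{args.seed}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stage_evaluate(cfg, run_dir / "classify", run_dir / "reduce",
                       run_dir / "manifest.csv", run_dir)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    shutil.copy(run_dir / "report.json", results / f"report_seed{args.seed}.json")
    shutil.copy(run_dir / "report.txt", results / f"report_seed{args.seed}.txt")

    report = io.read_json(run_dir / "report.json")
    s = report["sections"]
    cm, met = s["confusion_matrix"], s["classification_metrics"]
    print(f"confusion matrix: TP={cm['tp']} FN={cm['fn']} FP={cm['fp']} TN={cm['tn']}")
    print(f"sensitivity {met['sensitivity']}%  specificity {met['specificity']}%  "
          f"PPV {met['ppv']}%  NPV {met['npv']}%")
    hl = s["diagnostics"]["hosmer_lemeshow"]
    print(f"Nagelkerke R2 = {s['diagnostics']['nagelkerke_r2']:.3f}; "
          f"Hosmer-Lemeshow p = {hl['p']:.2f} (chi2={hl['chi2']:.2f}, df={hl['df']})")
    print("group comparison (F vs NF', Welch; FTF descriptive only):")
    labels = s["logistic_full"].get("labels", {})
    for comp, entry in s["group_scores"]["components"].items():
        groups = entry["groups"]
        line = "  ".join(
            f"{k}: {v['mean']:+.2f}+-{v['sd']:.2f}" for k, v in groups.items()
        )
        p = entry.get("welch_f_vs_nf", {}).get("p")
        print(f"  {comp} ({labels.get(comp, '?')}): {line}  p={p:.3f}"
              f"{'  FTF between group means' if entry.get('ftf_between') else ''}")


if __name__ == "__main__":
    main()
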