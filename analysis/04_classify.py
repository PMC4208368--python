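#!/usr/bin/env python
"""Binary logistic regression of fall status on the component scores.

Fits the full model on all retained components, selects predictors at
p < 0.1, refits, and writes both coefficient tables (beta, s.e., Wald, p,
exp(beta)) plus per-subject predicted probabilities.
"""

import argparse
import logging
import warnings
from pathlib import Path

from fallrisk.config import PipelineConfig
from fallrisk.pipeline import stage_classify
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
        stage_classify(cfg, run_dir / "reduce", run_dir / "manifest.csv",
                       run_dir / "classify")

    models = io.read_json(run_dir / "classify" / "logistic_models.json")
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    io.write_json(models, results / f"logistic_models_seed{args.seed}.json")

    for key in ("full", "reduced"):
        m = models[key]
        print(f"{key} model (n={m['n']}, Nagelkerke R2={m['nagelkerke_r2']:.3f})")
        for name, c in m["coefficients"].items():
            label = m.get("labels", {}).get(name, "")
            print(f"  {name:9s} {label:30s} beta={c['beta']:+.2f} se={c['se']:.2f} "
                  f"Wald={c['wald']:5.2f} p={c['p']:.3f} exp(beta)={c['exp_beta']:.2f}")
    print(f"classification uses the {models['model_choice']} model at threshold "
          f"{cfg.classification_threshold}")


if __name__ == "__main__":
    main()
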