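#!/usr/bin/env python
"""Simulate the synthetic study cohort (raw trials + manifest).

Generates 80 subjects (38 fallers, 42 non-fallers incl. 6 prospective
first-time fallers) with full raw signals: 6 walks of marker trajectories,
3x2 quiet-standing CoP traces, and 24 torque trials per subject. Raw trials
are bulky and land under scratch/; the manifest and a cohort summary go to
results/.

Run from the repository root: ``python analysis/01_simulate.py [--seed 1]``.
"""

import argparse
import logging
from pathlib import Path

from fallrisk.config import PipelineConfig
from fallrisk.pipeline import stage_simulate
from fallrisk import io

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    logging.basicConfig(level=logging.WARNING)

    cfg = PipelineConfig(seed=args.seed)
    run_dir = ROOT / "scratch" / f"run_seed{args.seed}"
    stage_simulate(cfg, run_dir)
    manifest = io.read_manifest(run_dir / "manifest.csv")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    manifest.to_csv(results / f"manifest_seed{args.seed}.csv")
    counts = manifest["group"].value_counts().to_dict()
    print(f"simulated cohort (seed {args.seed}) -> {run_dir}")
    print(f"  subjects: {len(manifest)} ({counts})")
    print(f"  first-time fallers carry fall_label=0 and follow_up_fall=1")


if __name__ == "__main__":
    main()
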