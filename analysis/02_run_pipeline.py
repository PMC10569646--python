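#!/usr/bin/env python
"""Run the full mating-gene pipeline over the simulated cohort.

Consumes the manifest written by 01_simulate_cohort.py, runs MAT-locus
classification, pheromone annotation and screening, receptor QC,
ancestral-state reconstruction and expression analysis, and writes the
cohort summary tables under results/pipeline/.  Finishes by comparing
the thallism calls against the planted states.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from pheromat import pipeline  # noqa: E402
from pheromat.synth import STRATEGY_TO_STATE  # noqa: E402

MANIFEST = ROOT / "scratch" / "cohort" / "manifest.yaml"
OUT = ROOT / "results" / "pipeline"


def main() -> None:
    if not MANIFEST.exists():
        sys.exit("run analysis/01_simulate_cohort.py first")
    out = pipeline.run_all(MANIFEST, OUT)
    thallism = pd.read_csv(OUT / "thallism_summary.tsv", sep="\t")
    states = pd.read_csv(MANIFEST.parent / "states.tsv", sep="\t", dtype=str)
    merged = thallism.merge(states, left_on="genome", right_on="taxon")
    merged["recovered"] = [
        STRATEGY_TO_STATE[s] == t for s, t in zip(merged["strategy"], merged["state"])
    ]
    print(merged[["genome", "strategy", "state", "recovered"]].to_string(index=False))
    n_ok = int(merged["recovered"].sum())
    print(f"\nthallism state recovered for {n_ok}/{len(merged)} genomes")
    alpha = pd.read_csv(OUT / "alpha_summary.tsv", sep="\t")
    print(f"alpha-factor classes: {alpha['class'].value_counts().to_dict()}")
    receptors = pd.read_csv(OUT / "receptor_summary.tsv", sep="\t")
    print(f"receptor verdicts: {receptors['verdict'].value_counts().to_dict()}")
    if "expression" in out:
        print(f"mating-dependence verdicts: {out['expression']}")
    print(f"\nsummary tables written to {OUT}")


if __name__ == "__main__":
    main()
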