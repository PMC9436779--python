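"""Co-driver enrichment on synthetic cohorts with planted odds ratios.

Simulates a 2,000-sample driver matrix in which five genes co-occur with
the full-length-amplification category (log2 OR = log2 3) — mirroring the
observation that amplification-driven tumours depend on cooperating
drivers while truncation acts alone — runs both enrichment tests, and
summarises null calibration over replicate null cohorts.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from fgfr2trunc.codriver_stats import run_enrichment
from fgfr2trunc.synthetic_cohort import simulate_driver_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "enrichment"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    s_effect, s_null = root.spawn(2)

    # planted effect: genes DRV00..DRV04 enriched in FL_AMP samples (OR 3)
    planted = np.concatenate([np.full(5, np.log(3.0)), np.zeros(15)])
    matrix, cats = simulate_driver_cohort(
        s_effect, 2000, n_genes=20, log_or={"FL_AMP": planted}
    )
    res = run_enrichment(matrix, cats)
    res.to_csv(OUT / "enrichment_planted_or3.tsv", sep="\t", index=False)
    hits = res[(res["category"] == "FL_AMP") & (res["q_fisher"] < 0.05)]
    print(f"planted OR=3 in FL_AMP for DRV00-DRV04: "
          f"{len(hits)} BH-significant co-occurrences in that category:")
    print(hits[["gene", "odds_ratio", "ci_low", "ci_high", "q_fisher"]]
          .round(3).to_string(index=False))

    # null calibration: 50 replicate cohorts with OR = 1 everywhere
    n_sig = n_tests = 0
    for child in s_null.spawn(50):
        m, c = simulate_driver_cohort(child, 2000, n_genes=20)
        r = run_enrichment(m, c)
        n_sig += int((r["q_fisher"] < 0.05).sum())
        n_tests += len(r)
    print(f"\nnull calibration: {n_sig}/{n_tests} "
          f"({100 * n_sig / n_tests:.2f}%) BH-significant calls at q<0.05 "
          f"across 50 null cohorts (expected <= 5%)")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    main(args.seed)
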