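#!/usr/bin/env python
"""Score every generated case with all six models and summarize the score
distributions and the difficulty-tier mix.

Reads results/cohort_144.csv; writes results/02_score_summary.csv.
"""

import pandas as pd

from ctoscore.io import read_cohort
from ctoscore.stats import tier_success_table

OUT = "results"


def main() -> None:
    cohort = read_cohort(f"{OUT}/cohort_144.csv")
    panels = [r.scores for r in cohort]
    df = pd.DataFrame(
        {
            "operator_cto": [p.operator_cto for p in panels],
            "jcto": [p.jcto for p in panels],
            "progress": [p.progress for p in panels],
            "ora": [p.ora for p in panels],
            "recharge": [p.recharge for p in panels],
            "cl": [p.cl for p in panels],
        }
    )
    summary = df.agg(["mean", "std", "min", "max"]).T.round(2)
    summary.to_csv(f"{OUT}/02_score_summary.csv")
    print("score distributions (n=144):")
    print(summary.to_string())

    table = tier_success_table(cohort)
    print("\ndifficulty-tier mix and technical success:")
    for row in table.rows:
        pct = "n/a" if row.technical_pct is None else f"{row.technical_pct}%"
        print(f"  {row.tier.label:<20} n={row.n:<4} success {pct}")


if __name__ == "__main__":
    main()
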