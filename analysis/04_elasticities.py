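"""Elasticity tables: full-sample matrix, expenditure vector, quintiles.

Reads the saved pipeline outputs (or refits if absent) and writes the
three standard table layouts: the n x n price-elasticity matrix with
significance stars, the expenditure-elasticity vector, and own-price
elasticities for the first and fifth income quintiles.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import ssbdemand as sd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--households", type=int, default=10_000)
    args = ap.parse_args()

    results = ROOT / "results"
    full = results / "elasticities_full_sample"
    if not full.with_suffix(".json").exists():
        import subprocess, sys

        subprocess.run(
            [sys.executable, str(ROOT / "analysis" / "03_fit_demand_system.py"),
             "--seed", str(args.seed), "--households", str(args.households)],
            check=True,
        )
    res = sd.read_elasticity_report(full)
    q1 = sd.read_elasticity_report(results / "elasticities_quintile_1")
    q5 = sd.read_elasticity_report(results / "elasticities_quintile_5")

    cats = list(res.categories)
    table4 = pd.DataFrame(
        {
            "category": cats,
            "expenditure_elasticity": res.expenditure_elasticities,
            "se": res.se_expenditure,
        }
    )
    table5 = pd.DataFrame(
        {
            "category": cats,
            "quintile_1": np.diag(q1.price_elasticities),
            "quintile_5": np.diag(q5.price_elasticities),
        }
    )
    table4.to_csv(results / "table_expenditure_elasticities.csv", index=False)
    table5.to_csv(results / "table_quintile_elasticities.csv", index=False)

    print("price-elasticity matrix (full sample):")
    print(
        pd.DataFrame(res.price_elasticities, index=cats, columns=cats)
        .round(3)
        .to_string()
    )
    print("\nexpenditure elasticities:")
    print(table4.round(3).to_string(index=False))
    print("\nown-price elasticities by income quintile:")
    print(table5.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
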