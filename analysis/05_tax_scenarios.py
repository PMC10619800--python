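"""First-order tax counterfactuals from the estimated elasticities.

For each scenario (a percent price change per category) the predicted
percent change in purchased quantities is Δq_i = Σ_j e_ij Δp_j.  Includes
the canonical policy experiment: a 20% price increase on ready-to-drink
sugar-sweetened beverages.
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
    args = ap.parse_args()

    results = ROOT / "results"
    path = results / "elasticities_full_sample"
    if not path.with_suffix(".json").exists():
        raise SystemExit("run analysis/03_fit_demand_system.py first")
    res = sd.read_elasticity_report(path)
    cats = list(res.categories)
    n = len(cats)

    scenarios = {}
    for pct in (10.0, 20.0, 30.0):
        dp = np.zeros(n)
        dp[cats.index("ssb_ready")] = pct
        scenarios[f"ssb_ready +{pct:.0f}%"] = dp
    dp_both = np.zeros(n)
    dp_both[cats.index("ssb_ready")] = 20.0
    dp_both[cats.index("ssb_prepared")] = 20.0
    scenarios["both SSB +20%"] = dp_both

    rows = []
    for name, dp in scenarios.items():
        dq = sd.tax_counterfactual(res, dp)
        rows.append({"scenario": name, **dict(zip(cats, dq))})
    out = pd.DataFrame(rows)
    out.to_csv(results / "tax_scenarios.csv", index=False)
    print("predicted % change in quantities purchased:")
    print(out.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
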