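"""Generate the default synthetic household budget survey.

Writes the purchase diary (large microdata) under scratch/ and the
generating truth (parameters, censoring targets) under results/, then
prints the realized purchase prevalences against their targets.
"""

import argparse
import json
from pathlib import Path

import numpy as np

import ssbdemand as sd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--households", type=int, default=10_000)
    args = ap.parse_args()

    truth = sd.make_default_truth(seed=args.seed, n_households=args.households)
    table = sd.simulate(truth)

    out_data = ROOT / "scratch" / "synthetic"
    out_data.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(out_data / "purchases.csv", index=False)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    truth.params.to_json(results / "truth_params.json")
    (results / "truth_scenario.json").write_text(
        json.dumps(
            {
                "n_goods": truth.n_goods,
                "n_households": truth.n_households,
                "seed": truth.seed,
                "prevalence_targets": truth.prevalence_targets.tolist(),
                "noise_scale": truth.noise_scale,
                "categories": list(table.config.categories),
            },
            indent=2,
        )
    )

    H = table.n_households
    print(f"simulated {H} households, {len(table.df)} purchase rows")
    print(f"microdata: {out_data / 'purchases.csv'}")
    for i, cat in enumerate(table.config.categories):
        prev = table.df.loc[table.df.category == cat, "household_id"].nunique() / H
        print(
            f"  {cat:<14} prevalence {100 * prev:5.1f}%  "
            f"(target {100 * truth.prevalence_targets[i]:5.1f}%)"
        )


if __name__ == "__main__":
    main()
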