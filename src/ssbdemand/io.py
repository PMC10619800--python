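"""Reading and writing household purchase microdata and elasticity reports.

The canonical input is a long-format table: one row per household x
category purchase, with expenditure, quantity acquired, geography and the
household covariates repeated on each row.  Absent (household, category)
pairs mean no recorded purchase.  A wide-format convenience reader pivots
to long immediately.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CategoryConfig

__all__ = [
    "PurchaseTable",
    "SchemaError",
    "read_purchases",
    "read_purchases_wide",
    "write_elasticity_report",
    "read_elasticity_report",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("household_id", "category", "expenditure", "quantity")


class SchemaError(ValueError):
    """Input file does not match the required purchase-table schema."""


@dataclass
class PurchaseTable:
    """Long-format household purchase diary.

    ``df`` holds one row per recorded (household, category) purchase with
    columns ``household_id, category, expenditure, quantity`` plus the
    geography/income/covariate columns named by ``config``.
    """

    df: pd.DataFrame
    config: CategoryConfig

    def __post_init__(self) -> None:
        missing = [c for c in self._required_columns() if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        bad = sorted(set(self.df["category"]) - set(self.config.categories))
        if bad:
            raise ValueError(f"unknown category label(s): {', '.join(map(str, bad))}")
        neg = (self.df["expenditure"] < 0) | (self.df["quantity"] < 0)
        if neg.any():
            raise ValueError(
                f"{int(neg.sum())} row(s) with negative expenditure or quantity"
            )

    def _required_columns(self) -> tuple[str, ...]:
        cfg = self.config
        return REQUIRED_COLUMNS + (
            cfg.state_column,
            cfg.region_column,
            cfg.income_column,
            *cfg.covariate_columns,
        )

    @property
    def n_households(self) -> int:
        return self.df["household_id"].nunique()

    def household_frame(self) -> pd.DataFrame:
        """One row per household with geography, income and covariates."""
        cfg = self.config
        cols = [
            "household_id",
            cfg.state_column,
            cfg.region_column,
            cfg.income_column,
            *cfg.covariate_columns,
        ]
        return (
            self.df[cols].drop_duplicates("household_id").set_index("household_id")
        )


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="", encoding="utf-8") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def read_purchases(path: str | Path, config: CategoryConfig) -> PurchaseTable:
    """Read a long-format purchase CSV/TSV into a validated table.

    Delimiter is auto-detected; a header row is required.  Rows with
    negative expenditure or quantity, unknown category labels, or missing
    schema columns raise informative errors.  Households with missing
    covariate values are dropped with a logged count (complete-case rule).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    required = REQUIRED_COLUMNS + (
        config.state_column,
        config.region_column,
        config.income_column,
        *config.covariate_columns,
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")

    check_cols = [
        "expenditure",
        "quantity",
        config.income_column,
        *config.covariate_columns,
    ]
    incomplete = df[check_cols].isna().any(axis=1)
    if incomplete.any():
        bad_households = set(df.loc[incomplete, "household_id"])
        n_before = df["household_id"].nunique()
        df = df[~df["household_id"].isin(bad_households)]
        logger.warning(
            "dropped %d of %d households with incomplete covariate/expenditure data",
            len(bad_households),
            n_before,
        )
    return PurchaseTable(df=df.reset_index(drop=True), config=config)


def read_purchases_wide(path: str | Path, config: CategoryConfig) -> PurchaseTable:
    """Read a wide table (one row per household, ``<cat>_expenditure`` /
    ``<cat>_quantity`` column pairs) and convert to the long canonical form.

    Zero-expenditure cells are treated as no purchase and omitted.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    id_cols = [
        "household_id",
        config.state_column,
        config.region_column,
        config.income_column,
        *config.covariate_columns,
    ]
    missing = [c for c in id_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    rows = []
    for cat in config.categories:
        ecol, qcol = f"{cat}_expenditure", f"{cat}_quantity"
        if ecol not in df.columns or qcol not in df.columns:
            raise SchemaError(f"{path.name}: missing column pair for category {cat!r}")
        sub = df[id_cols].copy()
        sub["category"] = cat
        sub["expenditure"] = df[ecol].to_numpy()
        sub["quantity"] = df[qcol].to_numpy()
        rows.append(sub[sub["expenditure"] > 0])
    long = pd.concat(rows, ignore_index=True)
    return PurchaseTable(df=long, config=config)


def _stars(z: float) -> str:
    from scipy.stats import norm

    p = 2.0 * norm.sf(abs(z))
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def write_elasticity_report(result, path: str | Path) -> None:
    """Write an elasticity result as a CSV matrix plus a JSON bundle.

    ``<path>.csv`` holds the n x n price-elasticity matrix with significance
    stars (p < 0.01/0.05/0.1, normal z-ratios) and an expenditure-elasticity
    column; ``<path>.json`` holds the full numeric payload for round-trips.
    Absent standard errors produce a star-free report and a logged warning.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cats = list(result.categories)
    n = len(cats)
    e = np.asarray(result.price_elasticities, dtype=float)
    se = result.se_price
    have_se = se is not None and np.all(np.isfinite(se))
    if not have_se:
        logger.warning("standard errors unavailable; writing report without stars")

    def cell(i: int, j: int) -> str:
        val = f"{e[i, j]:.4f}"
        if have_se and se[i, j] > 0:
            val += _stars(e[i, j] / se[i, j])
        return val

    with open(path.with_suffix(".csv"), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["category", *cats, "expenditure_elasticity"])
        for i, cat in enumerate(cats):
            row = [cat] + [cell(i, j) for j in range(n)]
            ee = f"{result.expenditure_elasticities[i]:.4f}"
            if have_se and result.se_expenditure is not None:
                sei = result.se_expenditure[i]
                if np.isfinite(sei) and sei > 0:
                    ee += _stars(result.expenditure_elasticities[i] / sei)
            row.append(ee)
            writer.writerow(row)

    payload = result.to_dict()
    with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def read_elasticity_report(path: str | Path):
    """Read back the JSON bundle written by :func:`write_elasticity_report`."""
    from .elasticities import ElasticityResult

    path = Path(path)
    with open(path.with_suffix(".json"), encoding="utf-8") as fh:
        payload = json.load(fh)
    return ElasticityResult.from_dict(payload)
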