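"""From purchase diaries to demand-system design matrices.

Households report expenditure and quantity per product category; prices are
not observed directly.  This module builds quality-adjusted unit values
(expenditure-weighted within household x category), imputes prices for
non-consuming households from the state → region → national mean of
observed unit values, computes expenditure shares and total food
expenditure, and evaluates the Törnqvist a(p) and Matsuda-style b(p) price
indices that deflate expenditure in the QUAIDS share equations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CategoryConfig
from .io import PurchaseTable

__all__ = [
    "PriceTable",
    "DemandSystemData",
    "compute_unit_values",
    "impute_prices",
    "assemble_system",
    "tornqvist_index",
    "matsuda_b_index",
]

logger = logging.getLogger(__name__)

IMPUTATION_LEVELS = ("observed", "state", "region", "national")


@dataclass
class PriceTable:
    """Household x category unit values with imputation provenance.

    ``unit_value`` is a household-indexed DataFrame (one column per
    category); cells are NaN until :func:`impute_prices` fills them.
    ``level`` holds the matching imputation provenance strings.
    """

    unit_value: pd.DataFrame
    level: pd.DataFrame

    @property
    def complete(self) -> bool:
        return bool(self.unit_value.notna().all().all())

    @property
    def n_imputed(self) -> int:
        return int((self.level.to_numpy() != "observed").sum())

    def to_long(self) -> pd.DataFrame:
        uv = self.unit_value.stack().rename("unit_value")
        lv = self.level.stack().rename("imputation_level")
        out = pd.concat([uv, lv], axis=1).reset_index()
        out.columns = ["household_id", "category", "unit_value", "imputation_level"]
        out["imputed"] = out["imputation_level"] != "observed"
        return out


def compute_unit_values(purchases: PurchaseTable) -> PriceTable:
    """Quality-adjusted unit values per household x category.

    A single purchase record gives expenditure / quantity.  Multiple
    records within a household x category give the expenditure-share
    weighted mean of the per-record unit prices.  Cells without purchases
    stay missing, flagged for imputation.
    """
    df = purchases.df
    bad = (df["quantity"] <= 0) & (df["expenditure"] > 0)
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise ValueError(
            f"expenditure > 0 with quantity = 0 in row(s) {rows} "
            "(cannot form a unit value)"
        )
    rec = df[df["expenditure"] > 0].copy()
    rec["unit_price"] = rec["expenditure"] / rec["quantity"]
    # expenditure-share weighted mean of per-record unit prices:
    # Σ e_k (e_k/q_k) / Σ e_k  (reduces to e/q for a single record)
    rec["_weighted"] = rec["expenditure"] * rec["unit_price"]
    sums = rec.groupby(["household_id", "category"])[["expenditure", "_weighted"]].sum()
    uv = (sums["_weighted"] / sums["expenditure"]).rename("unit_value")
    cats = list(purchases.config.categories)
    households = pd.Index(sorted(df["household_id"].unique()), name="household_id")
    wide = uv.unstack("category").reindex(index=households, columns=cats)
    level = pd.DataFrame(
        np.where(wide.notna(), "observed", ""), index=wide.index, columns=wide.columns
    )
    return PriceTable(unit_value=wide, level=level)


def impute_prices(prices: PriceTable, geography: pd.DataFrame) -> PriceTable:
    """Fill missing unit values from the state mean of observed values,
    falling back to the region mean, then the national mean.

    ``geography`` maps household_id (index) to ``state`` and ``region``
    columns.  Observed cells are never modified.  A category with no
    observed price anywhere raises, naming the category.
    """
    uv = prices.unit_value.copy()
    level = prices.level.copy()
    geo = geography.reindex(uv.index)
    if geo.isna().any().any():
        missing = uv.index[geo.isna().any(axis=1)].tolist()[:5]
        raise ValueError(f"geography missing for household(s) {missing}")
    state = geo.iloc[:, 0]
    region = geo.iloc[:, 1]

    for cat in uv.columns:
        col = uv[cat]
        observed = col.notna()
        if not observed.any():
            raise ValueError(
                f"category {cat!r} has no observed unit value anywhere; "
                "price imputation impossible"
            )
        state_means = col.groupby(state).mean()
        region_means = col.groupby(region).mean()
        national_mean = col.mean()
        for lvl, fill in (
            ("state", state.map(state_means)),
            ("region", region.map(region_means)),
            ("national", pd.Series(national_mean, index=col.index)),
        ):
            need = uv[cat].isna() & fill.notna()
            if need.any():
                uv.loc[need, cat] = fill[need]
                level.loc[need, cat] = lvl
        if uv[cat].isna().any():  # pragma: no cover - national mean always exists
            raise AssertionError("imputation chain left missing cells")
    if (uv.to_numpy() <= 0).any():
        raise ValueError("non-positive unit value after imputation")
    return PriceTable(unit_value=uv, level=level)


@dataclass
class DemandSystemData:
    """Per-household design matrices for the censored QUAIDS system.

    Attributes
    ----------
    w : (H, n) expenditure shares (rows sum to 1)
    lnp : (H, n) log unit values (post-imputation)
    lnm : (H,) log total food expenditure
    ln_a : (H,) Törnqvist price index ln a(p)
    b : (H,) Matsuda-style index b(p) (approximate, parameter-free mode)
    mean_shares : (n,) sample mean shares w̄
    base_log_prices : (n,) cross-household geometric-mean log prices ln p̄
    covariates : household covariate frame aligned with rows
    """

    w: np.ndarray
    lnp: np.ndarray
    lnm: np.ndarray
    ln_a: np.ndarray
    b: np.ndarray
    mean_shares: np.ndarray
    base_log_prices: np.ndarray
    categories: tuple[str, ...]
    household_ids: np.ndarray
    covariates: pd.DataFrame
    income: np.ndarray
    state: np.ndarray
    region: np.ndarray
    n_dropped: int = 0
    b_mode: str = "approx"

    @property
    def n_households(self) -> int:
        return self.w.shape[0]

    @property
    def n_goods(self) -> int:
        return self.w.shape[1]

    def consumption_indicators(self) -> np.ndarray:
        """(H, n) binary matrix: 1 where the household purchased good i."""
        return (self.w > 0).astype(float)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "categories": list(self.categories),
            "household_ids": self.household_ids.tolist(),
            "w": self.w.tolist(),
            "lnp": self.lnp.tolist(),
            "lnm": self.lnm.tolist(),
            "ln_a": self.ln_a.tolist(),
            "b": self.b.tolist(),
            "mean_shares": self.mean_shares.tolist(),
            "base_log_prices": self.base_log_prices.tolist(),
            "income": self.income.tolist(),
            "state": self.state.tolist(),
            "region": self.region.tolist(),
            "covariates": self.covariates.to_dict(orient="list"),
            "n_dropped": self.n_dropped,
            "b_mode": self.b_mode,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "DemandSystemData":
        d = json.loads(Path(path).read_text())
        return cls(
            w=np.asarray(d["w"], dtype=float),
            lnp=np.asarray(d["lnp"], dtype=float),
            lnm=np.asarray(d["lnm"], dtype=float),
            ln_a=np.asarray(d["ln_a"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            mean_shares=np.asarray(d["mean_shares"], dtype=float),
            base_log_prices=np.asarray(d["base_log_prices"], dtype=float),
            categories=tuple(d["categories"]),
            household_ids=np.asarray(d["household_ids"]),
            covariates=pd.DataFrame(d["covariates"]),
            income=np.asarray(d["income"], dtype=float),
            state=np.asarray(d["state"]),
            region=np.asarray(d["region"]),
            n_dropped=int(d["n_dropped"]),
            b_mode=d["b_mode"],
        )


def tornqvist_index(
    w: np.ndarray,
    lnp: np.ndarray,
    mean_shares: np.ndarray,
    base_log_prices: np.ndarray,
) -> np.ndarray:
    """Törnqvist price index per household.

    ln a(p_h) = Σ_i ½ (w_ih + w̄_i) (ln p_ih − ln p̄_i), with p̄ the
    cross-household geometric-mean price vector.  Equals 0 (index 1) when a
    household faces the base prices, regardless of shares.
    """
    weights = 0.5 * (np.asarray(w) + np.asarray(mean_shares)[None, :])
    dev = np.asarray(lnp) - np.asarray(base_log_prices)[None, :]
    return np.einsum("hi,hi->h", weights, dev)


def matsuda_b_index(
    w: np.ndarray,
    lnp: np.ndarray,
    mean_shares: np.ndarray,
    base_log_prices: np.ndarray,
    beta: np.ndarray | None = None,
    mode: str = "approx",
) -> np.ndarray:
    """Matsuda-style b(p) aggregator per household.

    ``approx`` (parameter-free): ln b = Σ_i ½ (w_ih − w̄_i)(ln p_ih − ln p̄_i),
    the deviation-weighted companion of the Törnqvist index.
    ``exact``: the Cobb–Douglas QUAIDS aggregator ln b = Σ_i β_i ln p_ih,
    requiring β (used inside iterated estimation).
    """
    if mode == "approx":
        weights = 0.5 * (np.asarray(w) - np.asarray(mean_shares)[None, :])
        dev = np.asarray(lnp) - np.asarray(base_log_prices)[None, :]
        return np.exp(np.einsum("hi,hi->h", weights, dev))
    if mode == "exact":
        if beta is None:
            raise ValueError("exact b(p) mode requires beta")
        return np.exp(np.asarray(lnp) @ np.asarray(beta))
    raise ValueError(f"unknown b(p) mode {mode!r}")


def assemble_system(
    purchases: PurchaseTable,
    prices: PriceTable,
    config: CategoryConfig,
) -> DemandSystemData:
    """Build shares, log prices, log expenditure and both price indices.

    Shares are observed expenditure over the household's total food
    expenditure (zero for non-purchases); households with no positive
    expenditure are dropped with a logged count.
    """
    if not prices.complete:
        raise ValueError("price table incomplete; run impute_prices first")
    df = purchases.df
    cats = list(config.categories)
    exp = (
        df.pivot_table(
            index="household_id",
            columns="category",
            values="expenditure",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=cats, fill_value=0.0)
        .reindex(index=prices.unit_value.index, fill_value=0.0)
    )
    m = exp.sum(axis=1)
    keep = m > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d household(s) with zero total food expenditure", n_dropped)
    exp = exp[keep]
    m = m[keep]
    if exp.empty:
        raise ValueError("no households with positive total food expenditure")

    w = exp.to_numpy() / m.to_numpy()[:, None]
    lnp = np.log(prices.unit_value.loc[exp.index, cats].to_numpy())
    mean_shares = w.mean(axis=0)
    base_log_prices = lnp.mean(axis=0)
    ln_a = tornqvist_index(w, lnp, mean_shares, base_log_prices)
    b = matsuda_b_index(w, lnp, mean_shares, base_log_prices, mode="approx")

    hh = purchases.household_frame().reindex(exp.index)
    return DemandSystemData(
        w=w,
        lnp=lnp,
        lnm=np.log(m.to_numpy()),
        ln_a=ln_a,
        b=b,
        mean_shares=mean_shares,
        base_log_prices=base_log_prices,
        categories=tuple(cats),
        household_ids=exp.index.to_numpy(),
        covariates=hh[list(config.covariate_columns)].reset_index(drop=True),
        income=hh[config.income_column].to_numpy(dtype=float),
        state=hh[config.state_column].to_numpy(),
        region=hh[config.region_column].to_numpy(),
        n_dropped=n_dropped,
    )
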