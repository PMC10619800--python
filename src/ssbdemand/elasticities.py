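"""Marshallian price and expenditure elasticities of the censored system.

Elasticities are evaluated at a representative point (sample or subgroup
means of shares, log prices, log expenditure, the price indices and the
probit cdf).  The price elasticity of good i w.r.t. the price of good j is

    e_ij = Φ̄_i · (∂w̃_i / ∂ln p_j) / w_i − δ_ij,

where w̃_i is the latent QUAIDS share and the derivative accounts for the
price dependence of the Törnqvist deflator a(p) (∂ln a/∂ln p_j = A_j, the
Törnqvist weight) and of the b(p) aggregator (∂ln b/∂ln p_j = B_j: β_j in
exact Cobb–Douglas mode, the deviation weight in approximate mode):

    ∂w̃_i/∂ln p_j = γ_ij − μ_i A_j − (λ_i x² / b) B_j,
    μ_i = β_i + 2 λ_i x / b,      x = ln(m / a(p)).

The expenditure elasticity is e_i = Φ̄_i μ_i / w_i + 1.  Standard errors
come from the delta method: the numeric gradient of each elasticity with
respect to the stacked parameters, propagated through the NLSUR
covariance (first-stage estimation uncertainty is not propagated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CategoryConfig
from .first_stage import ProbitResult
from .io import PurchaseTable
from .preprocessing import DemandSystemData
from .quaids import ParamLayout, QuaidsParams

__all__ = [
    "EvaluationPoint",
    "ElasticityResult",
    "price_elasticity",
    "expenditure_elasticity",
    "elasticity_matrix",
    "quintile_elasticities",
    "tax_counterfactual",
    "descriptive_tables",
]

logger = logging.getLogger(__name__)


@dataclass
class EvaluationPoint:
    """Representative point at which elasticities are evaluated."""

    shares: np.ndarray
    lnp: np.ndarray
    lnm: float
    ln_a: float
    b_approx: float
    cdf: np.ndarray
    pop_mean_shares: np.ndarray
    subgroup_label: str = "full sample"
    n_households: int = 0

    def __post_init__(self) -> None:
        if np.any(self.shares <= 0):
            raise ValueError(
                "evaluation point has non-positive shares; evaluate at "
                "(sub)sample means so every good has positive average share"
            )
        for name in ("shares", "lnp", "cdf", "pop_mean_shares"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite {name} in evaluation point")

    @property
    def x(self) -> float:
        return self.lnm - self.ln_a

    def b(self, params: QuaidsParams) -> float:
        if params.b_mode == "exact":
            return float(np.exp(self.lnp @ params.beta))
        return self.b_approx

    def tornqvist_weights(self) -> np.ndarray:
        """A_j = ∂ln a/∂ln p_j at the point."""
        return 0.5 * (self.shares + self.pop_mean_shares)

    def b_weights(self, params: QuaidsParams) -> np.ndarray:
        """B_j = ∂ln b/∂ln p_j at the point."""
        if params.b_mode == "exact":
            return params.beta
        return 0.5 * (self.shares - self.pop_mean_shares)

    def mu(self, params: QuaidsParams, variant: str = "scaled") -> np.ndarray:
        """μ_i = ∂w̃_i/∂ln m; ``scaled`` divides the quadratic term by b(p)
        (the Eq-3 derivative), ``plain`` omits the division."""
        if variant == "scaled":
            return params.beta + 2.0 * params.lambda_ * self.x / self.b(params)
        if variant == "plain":
            return params.beta + 2.0 * params.lambda_ * self.x
        raise ValueError(f"unknown mu variant {variant!r}")

    def to_dict(self) -> dict:
        return {
            "shares": self.shares.tolist(),
            "lnp": self.lnp.tolist(),
            "lnm": self.lnm,
            "ln_a": self.ln_a,
            "b_approx": self.b_approx,
            "cdf": self.cdf.tolist(),
            "pop_mean_shares": self.pop_mean_shares.tolist(),
            "subgroup_label": self.subgroup_label,
            "n_households": self.n_households,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationPoint":
        return cls(
            shares=np.asarray(d["shares"], float),
            lnp=np.asarray(d["lnp"], float),
            lnm=float(d["lnm"]),
            ln_a=float(d["ln_a"]),
            b_approx=float(d["b_approx"]),
            cdf=np.asarray(d["cdf"], float),
            pop_mean_shares=np.asarray(d["pop_mean_shares"], float),
            subgroup_label=d["subgroup_label"],
            n_households=int(d["n_households"]),
        )


@dataclass
class ElasticityResult:
    """n x n Marshallian price elasticities plus expenditure elasticities."""

    price_elasticities: np.ndarray
    expenditure_elasticities: np.ndarray
    se_price: np.ndarray | None
    se_expenditure: np.ndarray | None
    evaluation: EvaluationPoint
    categories: tuple[str, ...]
    derivation_mode: str = "analytic"

    def to_dict(self) -> dict:
        return {
            "price_elasticities": self.price_elasticities.tolist(),
            "expenditure_elasticities": self.expenditure_elasticities.tolist(),
            "se_price": None if self.se_price is None else self.se_price.tolist(),
            "se_expenditure": (
                None if self.se_expenditure is None else self.se_expenditure.tolist()
            ),
            "evaluation": self.evaluation.to_dict(),
            "categories": list(self.categories),
            "derivation_mode": self.derivation_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElasticityResult":
        return cls(
            price_elasticities=np.asarray(d["price_elasticities"], float),
            expenditure_elasticities=np.asarray(d["expenditure_elasticities"], float),
            se_price=None if d["se_price"] is None else np.asarray(d["se_price"], float),
            se_expenditure=(
                None
                if d["se_expenditure"] is None
                else np.asarray(d["se_expenditure"], float)
            ),
            evaluation=EvaluationPoint.from_dict(d["evaluation"]),
            categories=tuple(d["categories"]),
            derivation_mode=d["derivation_mode"],
        )


def build_evaluation_point(
    data: DemandSystemData,
    corrections: list[ProbitResult] | None = None,
    mask: np.ndarray | None = None,
    label: str = "full sample",
) -> EvaluationPoint:
    """Evaluation point from (sub)sample means.

    The Törnqvist weights keep the full-sample mean shares as the
    reference, so subgroup points deviate from the population base the same
    way the per-household index does.
    """
    if mask is None:
        mask = np.ones(data.n_households, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError(f"empty subgroup {label!r}")
    if corrections is None:
        cdf = np.ones(data.n_goods)
    else:
        cdf = np.array([c.cdf[mask].mean() for c in corrections])
    return EvaluationPoint(
        shares=data.w[mask].mean(axis=0),
        lnp=data.lnp[mask].mean(axis=0),
        lnm=float(data.lnm[mask].mean()),
        ln_a=float(data.ln_a[mask].mean()),
        b_approx=float(data.b[mask].mean()),
        cdf=cdf,
        pop_mean_shares=data.mean_shares,
        subgroup_label=label,
        n_households=int(mask.sum()),
    )


def _latent_share(params: QuaidsParams, point: EvaluationPoint, lnp, lnm):
    """Latent QUAIDS shares as a function of (lnp, lnm), with the price
    indices linearised at the evaluation point (weights held fixed)."""
    lnp = np.asarray(lnp, float)
    A = point.tornqvist_weights()
    B = point.b_weights(params)
    ln_a = point.ln_a + A @ (lnp - point.lnp)
    ln_b = np.log(point.b(params)) + B @ (lnp - point.lnp)
    x = lnm - ln_a
    return (
        params.alpha
        + params.gamma @ lnp
        + params.beta * x
        + params.lambda_ * x**2 / np.exp(ln_b)
    )


def price_elasticity(
    params: QuaidsParams,
    point: EvaluationPoint,
    i: int,
    j: int,
    mode: str = "analytic",
    mu_variant: str = "scaled",
) -> float:
    """Marshallian elasticity of good i w.r.t. the price of good j."""
    w_i = point.shares[i]
    if w_i <= 0:
        raise ValueError(f"share of good {i} non-positive at evaluation point")
    if mode == "numeric":
        h = 1e-6

        def f(step):
            lnp = point.lnp.copy()
            lnp[j] += step
            return _latent_share(params, point, lnp, point.lnm)[i]

        dw = (f(h) - f(-h)) / (2 * h)
    elif mode == "analytic":
        x = point.x
        b = point.b(params)
        mu_i = point.mu(params, mu_variant)[i]
        A = point.tornqvist_weights()
        B = point.b_weights(params)
        dw = params.gamma[i, j] - mu_i * A[j] - params.lambda_[i] * x**2 / b * B[j]
    else:
        raise ValueError(f"unknown derivation mode {mode!r}")
    return float(point.cdf[i] * dw / w_i - (1.0 if i == j else 0.0))


def expenditure_elasticity(
    params: QuaidsParams,
    point: EvaluationPoint,
    i: int,
    mode: str = "analytic",
    mu_variant: str = "scaled",
) -> float:
    """Total food expenditure elasticity of good i:
    e_i = Φ̄_i (β_i + 2λ_i ln(m/a)/b) / w_i + 1."""
    w_i = point.shares[i]
    if w_i <= 0:
        raise ValueError(f"share of good {i} non-positive at evaluation point")
    if mode == "numeric":
        h = 1e-6
        up = _latent_share(params, point, point.lnp, point.lnm + h)[i]
        dn = _latent_share(params, point, point.lnp, point.lnm - h)[i]
        mu_i = (up - dn) / (2 * h)
    else:
        mu_i = point.mu(params, mu_variant)[i]
    return float(point.cdf[i] * mu_i / w_i + 1.0)


def _all_elasticities(params, point, mu_variant="scaled"):
    """Vectorized analytic (n x n, n) elasticities at the point."""
    n = params.n
    x = point.x
    b = point.b(params)
    mu = point.mu(params, mu_variant)
    A = point.tornqvist_weights()
    B = point.b_weights(params)
    dw = params.gamma - np.outer(mu, A) - np.outer(params.lambda_ * x**2 / b, B)
    E = point.cdf[:, None] * dw / point.shares[:, None] - np.eye(n)
    e_m = point.cdf * mu / point.shares + 1.0
    return E, e_m


def _elasticity_gradients(params, point, mu_variant="scaled", h_rel=1e-6):
    """Numeric gradients of every elasticity w.r.t. the stacked parameters."""
    layout = params.layout
    psi0 = params.pack()
    n = params.n

    def values(psi):
        p = QuaidsParams.from_packed(
            psi, layout, categories=params.categories, b_mode=params.b_mode
        )
        E, e_m = _all_elasticities(p, point, mu_variant)
        return np.concatenate([E.ravel(), e_m])

    P = psi0.size
    grads = np.zeros((n * n + n, P))
    for k in range(P):
        h = h_rel * max(1.0, abs(psi0[k]))
        up = psi0.copy()
        dn = psi0.copy()
        up[k] += h
        dn[k] -= h
        grads[:, k] = (values(up) - values(dn)) / (2 * h)
    return grads


def elasticity_matrix(
    params: QuaidsParams,
    data: DemandSystemData,
    corrections: list[ProbitResult] | None = None,
    subgroup_mask: np.ndarray | None = None,
    label: str = "full sample",
    mu_variant: str = "scaled",
    compute_se: bool = True,
) -> ElasticityResult:
    """Full price-elasticity matrix and expenditure elasticities with
    delta-method standard errors, evaluated at (sub)sample means."""
    point = build_evaluation_point(data, corrections, subgroup_mask, label)
    E, e_m = _all_elasticities(params, point, mu_variant)
    se_price = se_exp = None
    if compute_se and params.vcov is not None:
        grads = _elasticity_gradients(params, point, mu_variant)
        var = np.einsum("kp,pq,kq->k", grads, params.vcov, grads)
        var = np.clip(var, 0.0, None)
        se = np.sqrt(var)
        n = params.n
        se_price = se[: n * n].reshape(n, n)
        se_exp = se[n * n :]
    return ElasticityResult(
        price_elasticities=E,
        expenditure_elasticities=e_m,
        se_price=se_price,
        se_expenditure=se_exp,
        evaluation=point,
        categories=tuple(params.categories) or tuple(data.categories),
        derivation_mode="analytic",
    )


def quintile_masks(income: np.ndarray, n_quantiles: int = 5) -> list[np.ndarray]:
    """Partition households into income quantile groups by rank, ties going
    to the lower group.  Masks partition the sample exactly."""
    from scipy.stats import rankdata

    income = np.asarray(income, float)
    if not np.all(np.isfinite(income)):
        raise ValueError("income must be finite for quantile ranking")
    H = income.size
    ranks = rankdata(income, method="min")
    bounds = np.ceil(np.arange(1, n_quantiles + 1) * H / n_quantiles)
    group = np.searchsorted(bounds, ranks, side="left")
    return [group == q for q in range(n_quantiles)]


def quintile_elasticities(
    params: QuaidsParams,
    data: DemandSystemData,
    corrections: list[ProbitResult] | None = None,
    income: np.ndarray | None = None,
    quantiles: tuple[int, ...] = (1, 5),
    mu_variant: str = "scaled",
    compute_se: bool = True,
) -> list[ElasticityResult]:
    """Elasticities at subgroup means of the requested income quintiles
    (1 = poorest fifth), reusing the full-sample parameters (no refit)."""
    income = data.income if income is None else np.asarray(income, float)
    masks = quintile_masks(income, 5)
    constant_income = bool(np.ptp(income) == 0)
    out = []
    for q in quantiles:
        mask = masks[q - 1]
        if not mask.any() and constant_income:
            # degenerate ranking: every household ties, all groups coincide
            mask = np.ones_like(mask)
        if mask.sum() < 30:
            logger.warning("income quintile %d has only %d households", q, mask.sum())
        out.append(
            elasticity_matrix(
                params,
                data,
                corrections,
                subgroup_mask=mask,
                label=f"income quintile {q}",
                mu_variant=mu_variant,
                compute_se=compute_se,
            )
        )
    return out


def tax_counterfactual(result: ElasticityResult, price_change: np.ndarray) -> np.ndarray:
    """First-order percent quantity changes from percent price changes:
    Δq_i (%) = Σ_j e_ij Δp_j (%)."""
    dp = np.asarray(price_change, float)
    return np.asarray(result.price_elasticities, float) @ dp


def descriptive_tables(
    purchases: PurchaseTable,
    config: CategoryConfig,
    ssb_pair: tuple[str, str] | None = None,
    group_columns: tuple[str, ...] | None = None,
) -> dict:
    """Consumption descriptives in the shape of survey summary tables.

    Per category: % of households purchasing, mean expenditure over all
    households, conditional mean over purchasers, and mean share of total
    food expenditure.  ``ssb_pair`` (default: first two categories) yields
    the joint-consumption percentage and per-subgroup breakdowns over
    ``group_columns`` (default: the region column).
    """
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
    )
    m = exp.sum(axis=1)
    exp = exp[m > 0]
    m = m[m > 0]
    H = len(exp)
    shares = exp.div(m, axis=0)

    table = pd.DataFrame(
        {
            "prevalence_pct": 100.0 * (exp > 0).mean(),
            "mean_expenditure": exp.mean(),
            "conditional_mean_expenditure": exp[exp > 0].mean(),
            "mean_share_pct": 100.0 * shares.mean(),
        }
    ).loc[cats]

    pair = ssb_pair or (cats[0], cats[1])
    joint = 100.0 * float(((exp[pair[0]] > 0) & (exp[pair[1]] > 0)).mean())

    hh = purchases.household_frame().reindex(exp.index)
    group_columns = group_columns or (config.region_column,)
    breakdowns = {}
    for gcol in group_columns:
        rows = []
        for gval, idx in hh.groupby(gcol).groups.items():
            sub = exp.loc[idx]
            subm = m.loc[idx]
            for cat in pair:
                buyers = sub[cat] > 0
                rows.append(
                    {
                        gcol: gval,
                        "category": cat,
                        "n": len(sub),
                        "prevalence_pct": 100.0 * buyers.mean(),
                        "mean_expenditure": sub[cat].mean(),
                        "conditional_mean_expenditure": (
                            sub.loc[buyers, cat].mean() if buyers.any() else np.nan
                        ),
                        "conditional_share_pct": (
                            100.0 * (sub.loc[buyers, cat] / subm[buyers]).mean()
                            if buyers.any()
                            else np.nan
                        ),
                    }
                )
        breakdowns[gcol] = pd.DataFrame(rows)

    return {
        "categories": table,
        "joint_consumption_pct": joint,
        "breakdowns": breakdowns,
        "n_households": H,
    }
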