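"""First-stage corrections for the censored demand system.

Two nuisances are handled before the share system is fit:

* zero purchases — a probit of the consumption decision per category
  (Shonkwiler–Yen step one) supplies the cdf Φ_i(z_h) that scales each
  latent share equation and the pdf φ_i(z_h) that enters as a regressor;
* endogenous total food expenditure — an OLS regression of ln m_h on
  household characteristics (Blundell–Robin) supplies the residual v̂_h
  included in every share equation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.stats import norm

from .preprocessing import DemandSystemData

__all__ = [
    "ProbitResult",
    "ExpenditureResidual",
    "fit_probit",
    "fit_all_probits",
    "blundell_robin_residual",
    "probit_coefficient_table",
]

logger = logging.getLogger(__name__)

# Φ clipped away from {0, 1} before use in the share system so the
# pdf-over-cdf geometry cannot degenerate; clip events are counted.
CDF_CLIP = 1e-9


@dataclass
class ProbitResult:
    """Fitted consumption-decision probit for one category."""

    category: str
    coefficients: np.ndarray
    cdf: np.ndarray
    pdf: np.ndarray
    converged: bool
    loglik: float
    n_clipped: int = 0
    regularized: bool = False


@dataclass
class ExpenditureResidual:
    """Blundell–Robin residual of ln total food expenditure."""

    vhat: np.ndarray
    first_stage_coefficients: np.ndarray
    r_squared: float


def _penalized_probit(y: np.ndarray, z: np.ndarray, alpha: float = 1e-4):
    """Tiny-L2 probit MLE fallback for (near-)separated responses."""

    def negloglik(b):
        xb = z @ b
        ll = np.sum(y * norm.logcdf(xb) + (1 - y) * norm.logcdf(-xb))
        return -ll + alpha * np.dot(b, b)

    res = minimize(negloglik, np.zeros(z.shape[1]), method="BFGS")
    return res.x, -res.fun


def fit_probit(consumed: np.ndarray, z: np.ndarray, category: str = "") -> ProbitResult:
    """Maximum-likelihood probit of the purchase decision.

    Returns the coefficient vector and the household-level cdf Φ and pdf φ
    evaluated at the fitted linear index.  Perfect separation falls back to
    a tiny-L2 penalized fit with a warning and the ``regularized`` flag set.
    """
    consumed = np.asarray(consumed, dtype=float)
    z = np.asarray(z, dtype=float)
    uniq = np.unique(consumed)
    if uniq.size < 2:
        raise ValueError(
            f"probit for {category or 'category'}: response takes a single value "
            f"({uniq[0]:g}); cannot fit a consumption decision model"
        )
    if np.linalg.matrix_rank(z) < z.shape[1]:
        raise ValueError(f"probit for {category or 'category'}: regressors not full rank")

    regularized = False
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Probit(consumed, z)
            fit = model.fit(disp=0, maxiter=200)
        coef = np.asarray(fit.params, dtype=float)
        loglik = float(fit.llf)
        converged = bool(fit.mle_retvals.get("converged", True))
        # a linear index beyond ~|40| means fitted probabilities of exactly
        # 0/1 — the signature of (quasi-)separation
        if (
            not np.all(np.isfinite(coef))
            or not converged
            or np.max(np.abs(z @ coef)) > 40.0
        ):
            raise np.linalg.LinAlgError("divergent coefficients")
    except Exception:  # separation or numerical failure
        logger.warning(
            "probit for %s: separation/failure detected; using tiny-L2 fallback",
            category or "category",
        )
        coef, loglik = _penalized_probit(consumed, z)
        regularized = True

    index = z @ coef
    cdf = norm.cdf(index)
    n_clipped = int(np.sum((cdf < CDF_CLIP) | (cdf > 1 - CDF_CLIP)))
    cdf = np.clip(cdf, CDF_CLIP, 1 - CDF_CLIP)
    pdf = norm.pdf(index)
    return ProbitResult(
        category=category,
        coefficients=coef,
        cdf=cdf,
        pdf=pdf,
        converged=converged,
        loglik=loglik,
        n_clipped=n_clipped,
        regularized=regularized,
    )


def probit_design(data: DemandSystemData) -> np.ndarray:
    """Default probit regressor matrix: intercept, covariates, and the
    household Törnqvist index (the price control in the decision model)."""
    z = np.column_stack(
        [
            np.ones(data.n_households),
            data.covariates.to_numpy(dtype=float),
            data.ln_a,
        ]
    )
    return z


def fit_all_probits(
    data: DemandSystemData,
    covariates: np.ndarray | None = None,
    allow_uncensored: bool = False,
) -> list[ProbitResult]:
    """One consumption-decision probit per category (indicator w_ih > 0).

    ``covariates`` defaults to :func:`probit_design` (intercept + household
    covariates + Törnqvist index).  Very-high-prevalence categories are
    still fitted; their convergence flag is surfaced on the result.  A
    category purchased by every household is an error unless
    ``allow_uncensored``, in which case it gets the degenerate correction
    Φ ≡ 1, φ ≡ 0 (no selection to correct).
    """
    z = probit_design(data) if covariates is None else np.asarray(covariates, float)
    indicators = data.consumption_indicators()
    results = []
    for i, cat in enumerate(data.categories):
        if allow_uncensored and indicators[:, i].min() == 1.0:
            results.append(
                ProbitResult(
                    category=cat,
                    coefficients=np.full(z.shape[1], np.nan),
                    cdf=np.ones(data.n_households),
                    pdf=np.zeros(data.n_households),
                    converged=True,
                    loglik=0.0,
                )
            )
            continue
        try:
            results.append(fit_probit(indicators[:, i], z, category=cat))
        except ValueError as err:
            raise ValueError(f"first stage failed for category {cat!r}: {err}") from err
    return results


def blundell_robin_residual(
    lnm: np.ndarray, household_chars: np.ndarray
) -> ExpenditureResidual:
    """OLS of ln total food expenditure on household characteristics.

    The residual v̂_h is the control function included in every share
    equation; with an intercept in the design it is exactly mean zero.
    Rank-deficient designs raise, listing the offending columns.
    """
    lnm = np.asarray(lnm, dtype=float)
    X = np.asarray(household_chars, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(j)
        raise ValueError(
            f"expenditure regression design is rank deficient; "
            f"collinear column index(es): {bad}"
        )
    fit = sm.OLS(lnm, X).fit()
    return ExpenditureResidual(
        vhat=np.asarray(fit.resid, dtype=float),
        first_stage_coefficients=np.asarray(fit.params, dtype=float),
        r_squared=float(fit.rsquared),
    )


def probit_coefficient_table(
    results: list[ProbitResult], regressor_names: list[str] | None = None
):
    """Coefficient table (category × regressor) for the fitted probits,
    the layout used to report the first-stage decision models."""
    import pandas as pd

    k = max(len(r.coefficients) for r in results)
    if regressor_names is None:
        regressor_names = ["intercept"] + [f"z{i}" for i in range(1, k)]
    rows = {r.category: r.coefficients for r in results}
    table = pd.DataFrame.from_dict(rows, orient="index", columns=regressor_names)
    table["converged"] = [r.converged for r in results]
    table["loglik"] = [r.loglik for r in results]
    return table


def expenditure_design(data: DemandSystemData) -> np.ndarray:
    """Default Blundell–Robin design: intercept, covariates, log income
    (no price index — prices belong to the share system, not the Engel
    first stage)."""
    cols = [np.ones(data.n_households), data.covariates.to_numpy(dtype=float)]
    log_income = np.log(np.clip(data.income, 1e-12, None))
    cov_names = [c.lower() for c in data.covariates.columns]
    if not any("income" in c for c in cov_names):
        cols.append(log_income)
    return np.column_stack(cols)
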