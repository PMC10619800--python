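"""Synthetic household budget microdata with known demand structure.

The generator emulates the statistical structure a censored QUAIDS
analysis of purchase-diary data assumes: expenditure shares driven by a
known parameter set through the share equations, state-level price
variation (27 states grouped into 5 regions, mirroring the geography used
for price imputation fallbacks), probit-driven censoring producing
realistic zero-purchase prevalence, and total food expenditure that is
endogenous through a shock shared with the share disturbances.  Because
the generating parameters are known, the full pipeline can be validated
end-to-end by parameter and elasticity recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import CategoryConfig
from .io import PurchaseTable
from .quaids import QuaidsParams

__all__ = [
    "SyntheticTruth",
    "make_default_truth",
    "simulate",
    "truth_config",
    "recovery_experiment",
]

COVARIATE_COLUMNS = ("urban", "log_income", "educ_years", "n_children", "credit_card")

# Brazilian-style geography: 27 states in 5 regions
REGION_SIZES = (7, 9, 4, 4, 3)


@dataclass
class SyntheticTruth:
    """Generating model: the oracle against which recovery is judged.

    ``params.theta`` loads the expenditure shock into the share
    disturbances (endogeneity); ``params.rho`` loads each good's censoring
    shock into its share disturbance, which is exactly the coefficient the
    Shonkwiler–Yen pdf regressor recovers.
    """

    params: QuaidsParams
    probit_slopes: np.ndarray  # n x k on (urban, log_income_c, educ_c, n_children)
    prevalence_targets: np.ndarray
    base_log_prices: np.ndarray
    state_price_sd: float = 0.12
    household_price_sd: float = 0.08
    expenditure_coefficients: dict = field(default_factory=dict)
    expenditure_shock_sd: float = 0.35
    noise_scale: float = 0.02
    n_goods: int = 4
    n_households: int = 10_000
    seed: int = 0
    censoring: bool = True
    # what happens to the budget of a censored purchase: "reallocate" moves
    # it into the residual food category (the diary's total food budget is
    # what it is), "shrink" removes it from observed total expenditure
    censored_budget: str = "reallocate"

    def __post_init__(self) -> None:
        p = self.params
        assert abs(p.alpha.sum() - 1.0) < 1e-12
        assert abs(p.beta.sum()) < 1e-12
        assert abs(p.lambda_.sum()) < 1e-12
        assert np.allclose(p.gamma, p.gamma.T)
        assert np.allclose(p.gamma.sum(axis=1), 0.0)


def default_categories(n_goods: int) -> tuple[str, ...]:
    if n_goods == 4:
        return ("ssb_ready", "ssb_prepared", "milk", "other_foods")
    return tuple(f"good_{i + 1}" for i in range(n_goods - 1)) + ("other_foods",)


def truth_config(truth: SyntheticTruth) -> CategoryConfig:
    """The CategoryConfig matching the generator's output columns."""
    return CategoryConfig(
        categories=default_categories(truth.n_goods),
        covariate_columns=COVARIATE_COLUMNS,
        reference_category=default_categories(truth.n_goods)[-1],
    )


def make_default_truth(
    n_goods: int = 4, seed: int = 0, n_households: int = 10_000
) -> SyntheticTruth:
    """Default scenario: one high-share residual good (the "other foods"
    role, latent mean share ≈ 0.71) and censoring targets spanning roughly
    15%–99% purchase prevalence, the shape of a week-long purchase diary.
    """
    if n_goods < 2:
        raise ValueError("need at least 2 goods")
    rng = np.random.default_rng(seed)
    expenditure_coefficients = {
        "const": 2.0,
        "log_income_c": 0.45,
        "urban": 0.15,
        "educ_c": 0.01,
    }
    # expected ln(m/a): the Törnqvist index is a relative index (mean ~0),
    # so x carries the log-expenditure level
    x0 = expenditure_coefficients["const"] + 0.84 * expenditure_coefficients["urban"]
    if n_goods == 4:
        target_shares = np.array([0.10, 0.07, 0.12, 0.71])
        gamma = np.array(
            [
                [0.040, -0.010, -0.010, -0.020],
                [-0.010, 0.030, 0.000, -0.020],
                [-0.010, 0.000, 0.050, -0.040],
                [-0.020, -0.020, -0.040, 0.080],
            ]
        )
        beta = np.array([-0.020, -0.015, -0.010, 0.045])
        lambda_ = np.array([0.004, 0.003, 0.002, -0.009])
        theta = np.array([0.010, -0.005, 0.005, -0.010])
        rho = np.array([0.010, 0.008, 0.005, 0.000])
        prevalence = np.array([0.25, 0.15, 0.45, 0.99])
        base_lnp = np.array([0.7, 0.0, 0.3, 1.1])
    else:
        # generic small-system construction with the same shape
        n = n_goods
        target_shares = np.full(n, 0.25 / (n - 1))
        target_shares[-1] = 1.0 - target_shares[:-1].sum()
        raw = rng.normal(0.0, 0.02, size=(n, n))
        gamma = 0.5 * (raw + raw.T)
        gamma -= gamma.mean(axis=1, keepdims=True)  # homogeneity
        gamma = 0.5 * (gamma + gamma.T)
        # iterate symmetrize + row-center to satisfy both exactly
        for _ in range(200):
            gamma -= gamma.mean(axis=1, keepdims=True)
            gamma = 0.5 * (gamma + gamma.T)
        beta = rng.normal(0.0, 0.01, n)
        beta -= beta.mean()
        lambda_ = rng.normal(0.0, 0.003, n)
        lambda_ -= lambda_.mean()
        theta = rng.normal(0.0, 0.008, n)
        theta -= theta.mean()
        rho = np.concatenate([np.abs(rng.normal(0.0, 0.008, n - 1)), [0.0]])
        prevalence = np.concatenate(
            [np.linspace(0.15, 0.6, n - 1), [0.99]]
        )
        base_lnp = rng.normal(0.5, 0.3, n)
    # calibrate intercepts so latent shares at mean prices/expenditure hit
    # the targets; adding-up is preserved because the γ columns, β and λ
    # each sum to zero and the targets sum to one
    b0 = float(np.exp(base_lnp @ beta))
    alpha = target_shares - gamma @ base_lnp - beta * x0 - lambda_ * x0**2 / b0
    params = QuaidsParams(
        alpha=alpha,
        gamma=gamma,
        beta=beta,
        lambda_=lambda_,
        theta=theta,
        rho=rho,
        categories=default_categories(n_goods),
        b_mode="exact",
    )
    slopes = np.column_stack(
        [
            rng.normal(0.25, 0.05, n_goods),   # urban
            rng.normal(0.20, 0.05, n_goods),   # centred log income
            rng.normal(0.02, 0.01, n_goods),   # centred education
            rng.normal(0.10, 0.03, n_goods),   # children
        ]
    )
    return SyntheticTruth(
        params=params,
        probit_slopes=slopes,
        prevalence_targets=prevalence,
        base_log_prices=base_lnp,
        expenditure_coefficients=expenditure_coefficients,
        n_goods=n_goods,
        n_households=n_households,
        seed=seed,
    )


def _draw_covariates(rng, H):
    urban = rng.binomial(1, 0.84, H).astype(float)
    log_income = rng.normal(7.6, 0.7, H)
    educ = np.clip(rng.normal(9.0, 4.0, H), 0.0, 20.0)
    children = rng.poisson(0.8, H).astype(float)
    card = rng.binomial(1, 0.5, H).astype(float)
    return pd.DataFrame(
        {
            "urban": urban,
            "log_income": log_income,
            "educ_years": educ,
            "n_children": children,
            "credit_card": card,
        }
    )


def simulate(truth: SyntheticTruth, return_internals: bool = False):
    """Generate a long-format :class:`PurchaseTable` from the truth.

    Latent shares solve the share equations at the same Törnqvist index the
    pipeline computes (a fixed point over the sample), the endogeneity term
    uses the in-sample expenditure residual, and censored purchases are
    zeroed with quantities derived as expenditure / price so unit values
    reproduce the drawn prices exactly.  Same seed, same table.
    """
    rng = np.random.default_rng(truth.seed)
    H, n = truth.n_households, truth.n_goods
    p = truth.params

    cov = _draw_covariates(rng, H)
    states = rng.integers(0, 27, H)
    region_of_state = np.repeat(np.arange(5), REGION_SIZES)
    state_labels = np.array([f"S{k + 1:02d}" for k in range(27)])
    region_labels = np.array([f"R{k + 1}" for k in range(5)])

    # prices: state-level log means + household noise
    state_eff = rng.normal(0.0, truth.state_price_sd, size=(27, n))
    lnp = (
        truth.base_log_prices[None, :]
        + state_eff[states]
        + rng.normal(0.0, truth.household_price_sd, size=(H, n))
    )

    # endogenous total food expenditure
    c = truth.expenditure_coefficients
    u = rng.normal(0.0, truth.expenditure_shock_sd, H)
    lnm = (
        c["const"]
        + c["log_income_c"] * (cov["log_income"].to_numpy() - 7.6)
        + c["urban"] * cov["urban"].to_numpy()
        + c["educ_c"] * (cov["educ_years"].to_numpy() - 9.0)
        + u
    )
    # in-sample expenditure residual (what the Engel first stage recovers)
    Z = np.column_stack([np.ones(H), cov.to_numpy(dtype=float)])
    coef, *_ = np.linalg.lstsq(Z, lnm, rcond=None)
    vhat = lnm - Z @ coef

    # censoring shocks and decisions
    zc = np.column_stack(
        [
            cov["urban"].to_numpy(),
            cov["log_income"].to_numpy() - 7.6,
            cov["educ_years"].to_numpy() - 9.0,
            cov["n_children"].to_numpy(),
        ]
    )
    probit_index = zc @ truth.probit_slopes.T  # H x n, before intercept
    zeta = rng.normal(0.0, 1.0, size=(H, n))
    intercepts = np.array(
        [
            -np.quantile(probit_index[:, i] + zeta[:, i], 1.0 - truth.prevalence_targets[i])
            for i in range(n)
        ]
    )
    latent_idx = probit_index + intercepts[None, :] + zeta
    consume = latent_idx > 0 if truth.censoring else np.ones((H, n), dtype=bool)

    # share disturbances: endogeneity + censoring loading + idiosyncratic,
    # last good absorbs so shares sum to one exactly.
    # θ is the coefficient of v̂ in the observed-share equation; under
    # discrete censoring the latent loading must be θ_i/Φ_i(z) so that
    # E[D_i · θ_i v̂ / Φ_i] = θ_i v̂ survives selection unattenuated.
    # ρ_i ζ_i likewise delivers exactly ρ_i φ_i(z) after selection.
    eps = np.zeros((H, n))
    eps[:, :-1] = truth.noise_scale * rng.normal(0.0, 1.0, size=(H, n - 1))
    cdf_z = norm.cdf(probit_index + intercepts[None, :]) if truth.censoring else np.ones((H, n))
    if truth.censoring:
        eps[:, :-1] += p.rho[None, :-1] * zeta[:, :-1]
    eps[:, :-1] += vhat[:, None] * (
        p.theta[None, :-1] / np.clip(cdf_z[:, :-1], 0.02, 1.0)
    )
    eps[:, -1] = -eps[:, :-1].sum(axis=1)

    # fixed point: shares and the Törnqvist index determine each other
    base_lnp_hat = lnp.mean(axis=0)
    w = np.tile(p.alpha, (H, 1))
    b = np.exp(lnp @ p.beta)
    for _ in range(500):
        wbar = w.mean(axis=0)
        ln_a = np.einsum(
            "hi,hi->h", 0.5 * (w + wbar[None, :]), lnp - base_lnp_hat[None, :]
        )
        x = lnm - ln_a
        latent = (
            p.alpha[None, :]
            + lnp @ p.gamma.T
            + np.outer(x, p.beta)
            + np.outer(x**2 / b, p.lambda_)
        )
        w_new = latent + eps
        if np.max(np.abs(w_new - w)) < 1e-13:
            w = w_new
            break
        w = w_new

    neg_frac = float(np.mean((w < 0).any(axis=1)))
    if neg_frac > 0.01:
        raise ValueError(
            f"{100 * neg_frac:.1f}% of households have a negative latent share; "
            "reduce noise/price dispersion or move mean shares away from 0"
        )

    m = np.exp(lnm)
    expenditure = np.clip(w, 0.0, None) * m[:, None] * consume
    if truth.censoring and truth.censored_budget == "reallocate":
        spent_small = expenditure[:, :-1].sum(axis=1)
        expenditure[:, -1] = consume[:, -1] * np.clip(m - spent_small, 0.0, None)
    prices = np.exp(lnp)
    quantity = expenditure / prices

    hh = pd.DataFrame(
        {
            "household_id": np.arange(H),
            "state": state_labels[states],
            "region": region_labels[region_of_state[states]],
            "income": np.exp(cov["log_income"].to_numpy()),
        }
    )
    hh = pd.concat([hh, cov], axis=1)
    cats = default_categories(n)
    frames = []
    for i, cat in enumerate(cats):
        mask = expenditure[:, i] > 0
        sub = hh[mask].copy()
        sub["category"] = cat
        sub["expenditure"] = expenditure[mask, i]
        sub["quantity"] = quantity[mask, i]
        frames.append(sub)
    long = pd.concat(frames, ignore_index=True)
    table = PurchaseTable(df=long, config=truth_config(truth))
    if not return_internals:
        return table
    internals = {
        "latent_shares": w,
        "lnp": lnp,
        "lnm": lnm,
        "vhat": vhat,
        "expenditure_shock": u,
        "consume": consume,
        "true_cdf": norm.cdf(probit_index + intercepts[None, :]),
        "ln_a": ln_a,
        "b": b,
        "household": hh,
    }
    return table, internals


def true_elasticities(truth: SyntheticTruth, data, internals=None):
    """Elasticities implied by the generating parameters, evaluated at the
    same kind of point the pipeline uses (sample means of the fitted data,
    true probit purchase probabilities)."""
    from .elasticities import EvaluationPoint, _all_elasticities

    if truth.censoring and internals is not None:
        ids = np.asarray(data.household_ids, dtype=int)
        cdf = internals["true_cdf"][ids].mean(axis=0)
    else:
        cdf = np.ones(truth.n_goods)
    point = EvaluationPoint(
        shares=data.w.mean(axis=0),
        lnp=data.lnp.mean(axis=0),
        lnm=float(data.lnm.mean()),
        ln_a=float(data.ln_a.mean()),
        b_approx=float(data.b.mean()),
        cdf=cdf,
        pop_mean_shares=data.mean_shares,
        subgroup_label="truth",
        n_households=data.n_households,
    )
    E, e_m = _all_elasticities(truth.params, point)
    return E, e_m, point


def recovery_experiment(
    truth: SyntheticTruth,
    H: int | None = None,
    n_replicates: int = 20,
    seed: int = 0,
) -> dict:
    """Simulate → full pipeline → compare estimates with the truth.

    Returns elementwise parameter bias/RMSE, 95%-interval coverage, and
    own-price elasticity bias (per good and its median absolute value).
    """
    from .pipeline import fit_pipeline

    if H is None:
        H = truth.n_households
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_replicates)
    t = truth.params
    psi_true = None
    psi_hats, covered, eii_err, zscores = [], [], [], []
    for rep_seed in seeds:
        rep_truth = replace(truth, n_households=H, seed=int(rep_seed))
        table, internals = simulate(rep_truth, return_internals=True)
        res = fit_pipeline(table)
        if psi_true is None:
            psi_true = res.params.layout.pack(
                t.alpha, t.gamma, t.beta, t.lambda_, t.theta, t.rho
            )
        psi_hat = res.params.pack()
        psi_hats.append(psi_hat)
        se = np.sqrt(np.clip(np.diag(res.params.vcov), 0.0, None))
        ok = se > 1e-12
        covered.append(
            (np.abs(psi_hat - psi_true)[ok] <= 1.96 * se[ok]).astype(float)
        )
        z = np.full(psi_true.shape, np.nan)
        z[ok] = np.abs(psi_hat - psi_true)[ok] / se[ok]
        zscores.append(z)
        E_true, _, _ = true_elasticities(rep_truth, res.data, internals)
        E_hat = res.elasticities.price_elasticities
        eii_err.append(np.diag(E_hat) - np.diag(E_true))
    psi_hats = np.array(psi_hats)
    eii_err = np.array(eii_err)
    bias = psi_hats.mean(axis=0) - psi_true
    rmse = np.sqrt(((psi_hats - psi_true) ** 2).mean(axis=0))
    own_bias = eii_err.mean(axis=0)
    # per-element |error| / SE, median across replicates (pinned parameters
    # with zero SE stay NaN)
    zarr = np.array(zscores)
    median_abs_z = np.full(zarr.shape[1], np.nan)
    has_z = np.isfinite(zarr).any(axis=0)
    if has_z.any():
        median_abs_z[has_z] = np.nanmedian(zarr[:, has_z], axis=0)
    return {
        "param_bias": bias,
        "param_rmse": rmse,
        "param_median_abs_z": median_abs_z,
        "coverage": float(np.concatenate(covered).mean()),
        "own_price_bias": own_bias,
        "own_price_median_abs_bias": float(np.median(np.abs(own_bias))),
        "own_price_errors": eii_err,
        "psi_true": psi_true,
        "psi_hats": psi_hats,
        "n_replicates": n_replicates,
        "H": H,
    }
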