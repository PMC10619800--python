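"""Censored QUAIDS share system and its NLSUR estimator.

The observed share of good i for household h is modelled as

    w_ih = Φ_i(z_h) [ α_i + Σ_j γ_ij ln p_jh + β_i x_h + (λ_i / b_h) x_h² ]
           + θ_i v̂_h + ρ_i φ_i(z_h) + ξ_ih,

with x_h = ln(m_h / a(p_h)), a(p) the Törnqvist index, b(p) the Matsuda
aggregator (exact Cobb–Douglas Π p^β or the parameter-free approximate
index), Φ_i/φ_i the first-stage probit cdf/pdf (Shonkwiler–Yen) and v̂ the
Blundell–Robin expenditure residual.  Given the indices and first-stage
quantities the system is linear in the parameters, so estimation proceeds
by iterated feasible GLS: solve the (restricted) linear GLS problem, update
the cross-equation residual covariance Σ̂ and — in exact-b mode — the b_h
aggregator from the current β, and repeat to a fixed point.  Adding-up,
homogeneity and symmetry are linear restrictions imposed by
null-space reparameterization.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import null_space

from .first_stage import ExpenditureResidual, ProbitResult
from .preprocessing import DemandSystemData, matsuda_b_index

__all__ = [
    "ParamLayout",
    "QuaidsParams",
    "FitDiagnostics",
    "NlsurOptions",
    "predict_shares",
    "nlsur_fit",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParamLayout:
    """Index arithmetic for the stacked parameter vector.

    Equation i occupies a contiguous block
    ``[α_i, γ_i1..γ_in, β_i, λ_i, (θ_i), (ρ_i)]``.
    """

    n: int
    include_theta: bool = True
    include_rho: bool = True

    @property
    def k_eq(self) -> int:
        return self.n + 3 + int(self.include_theta) + int(self.include_rho)

    @property
    def size(self) -> int:
        return self.n * self.k_eq

    def alpha(self, i: int) -> int:
        return i * self.k_eq

    def gamma(self, i: int, j: int) -> int:
        return i * self.k_eq + 1 + j

    def beta(self, i: int) -> int:
        return i * self.k_eq + 1 + self.n

    def lambda_(self, i: int) -> int:
        return i * self.k_eq + 2 + self.n

    def theta(self, i: int) -> int:
        if not self.include_theta:
            raise IndexError("theta not included in layout")
        return i * self.k_eq + 3 + self.n

    def rho(self, i: int) -> int:
        if not self.include_rho:
            raise IndexError("rho not included in layout")
        return i * self.k_eq + 3 + self.n + int(self.include_theta)

    def pack(self, alpha, gamma, beta, lambda_, theta=None, rho=None) -> np.ndarray:
        psi = np.zeros(self.size)
        for i in range(self.n):
            psi[self.alpha(i)] = alpha[i]
            for j in range(self.n):
                psi[self.gamma(i, j)] = gamma[i, j]
            psi[self.beta(i)] = beta[i]
            psi[self.lambda_(i)] = lambda_[i]
            if self.include_theta:
                psi[self.theta(i)] = 0.0 if theta is None else theta[i]
            if self.include_rho:
                psi[self.rho(i)] = 0.0 if rho is None else rho[i]
        return psi

    def unpack(self, psi: np.ndarray) -> dict:
        n = self.n
        out = {
            "alpha": np.array([psi[self.alpha(i)] for i in range(n)]),
            "gamma": np.array(
                [[psi[self.gamma(i, j)] for j in range(n)] for i in range(n)]
            ),
            "beta": np.array([psi[self.beta(i)] for i in range(n)]),
            "lambda_": np.array([psi[self.lambda_(i)] for i in range(n)]),
            "theta": np.zeros(n),
            "rho": np.zeros(n),
        }
        if self.include_theta:
            out["theta"] = np.array([psi[self.theta(i)] for i in range(n)])
        if self.include_rho:
            out["rho"] = np.array([psi[self.rho(i)] for i in range(n)])
        return out


@dataclass
class QuaidsParams:
    """Full parameter set of the censored QUAIDS system plus covariance.

    ``vcov`` is over the stacked parameter vector in :class:`ParamLayout`
    order (restricted parameters carry the reduced-rank covariance
    ``R V_free R'``).
    """

    alpha: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    lambda_: np.ndarray
    theta: np.ndarray
    rho: np.ndarray
    vcov: np.ndarray | None = None
    restrictions: dict = field(default_factory=dict)
    categories: tuple[str, ...] = ()
    b_mode: str = "exact"
    include_theta: bool = True
    include_rho: bool = True

    @property
    def n(self) -> int:
        return len(self.alpha)

    @property
    def layout(self) -> ParamLayout:
        return ParamLayout(self.n, self.include_theta, self.include_rho)

    def pack(self) -> np.ndarray:
        return self.layout.pack(
            self.alpha, self.gamma, self.beta, self.lambda_, self.theta, self.rho
        )

    @classmethod
    def from_packed(
        cls,
        psi: np.ndarray,
        layout: ParamLayout,
        **kwargs,
    ) -> "QuaidsParams":
        parts = layout.unpack(psi)
        return cls(
            include_theta=layout.include_theta,
            include_rho=layout.include_rho,
            **parts,
            **kwargs,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha": self.alpha.tolist(),
            "gamma": self.gamma.tolist(),
            "beta": self.beta.tolist(),
            "lambda": self.lambda_.tolist(),
            "theta": self.theta.tolist(),
            "rho": self.rho.tolist(),
            "vcov": None if self.vcov is None else self.vcov.tolist(),
            "restrictions": self.restrictions,
            "categories": list(self.categories),
            "b_mode": self.b_mode,
            "include_theta": self.include_theta,
            "include_rho": self.include_rho,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "QuaidsParams":
        d = json.loads(Path(path).read_text())
        return cls(
            alpha=np.asarray(d["alpha"], float),
            gamma=np.asarray(d["gamma"], float),
            beta=np.asarray(d["beta"], float),
            lambda_=np.asarray(d["lambda"], float),
            theta=np.asarray(d["theta"], float),
            rho=np.asarray(d["rho"], float),
            vcov=None if d["vcov"] is None else np.asarray(d["vcov"], float),
            restrictions=d["restrictions"],
            categories=tuple(d["categories"]),
            b_mode=d["b_mode"],
            include_theta=d["include_theta"],
            include_rho=d["include_rho"],
        )


@dataclass
class FitDiagnostics:
    """Per-equation goodness of fit and convergence bookkeeping."""

    r_squared: np.ndarray
    rmse: np.ndarray
    mae: np.ndarray
    iterations: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)
    sigma: np.ndarray | None = None
    sigma_repaired: bool = False


@dataclass
class NlsurOptions:
    """Estimation options.

    ``sigma_iterations`` controls the feasible-GLS weighting: 1 is the
    classical two-step estimator (NLS, then one GLS step with Σ̂ from the
    NLS residuals — the default of Stata's nlsur); larger values iterate
    Σ̂ further, and ``None`` iterates to a joint fixed point.  Fully
    iterating is appropriate for the uncensored system but degenerate for
    censored share data: observed shares sum to one identically while the
    censored model does not add up, so iterating drives unbounded GLS
    weight onto the adding-up combination and collapses the fit onto it.
    """

    impose_homogeneity: bool = True
    impose_symmetry: bool = True
    impose_adding_up: bool = True
    b_mode: str = "exact"
    tol: float = 1e-6
    max_iter: int = 100
    sigma_iterations: int | None = 1
    drop_equation: int | None = None
    constrain_theta_sum: bool = False


def build_constraints(
    layout: ParamLayout,
    options: NlsurOptions,
    pinned_zero: tuple[int, ...] = (),
):
    """Linear equality constraints A ψ = c for the requested restrictions.

    ``pinned_zero`` lists parameter indices fixed at zero (used for
    coefficients whose regressor column is identically zero, e.g. the pdf
    coefficient of an uncensored category).
    """
    rows, rhs = [], []
    n, P = layout.n, layout.size

    def row():
        return np.zeros(P)

    if options.impose_adding_up:
        r = row()
        for i in range(n):
            r[layout.alpha(i)] = 1.0
        rows.append(r)
        rhs.append(1.0)
        for name in ("beta", "lambda_"):
            r = row()
            for i in range(n):
                r[getattr(layout, name)(i)] = 1.0
            rows.append(r)
            rhs.append(0.0)
        for j in range(n):
            r = row()
            for i in range(n):
                r[layout.gamma(i, j)] = 1.0
            rows.append(r)
            rhs.append(0.0)
    if options.constrain_theta_sum and layout.include_theta:
        r = row()
        for i in range(n):
            r[layout.theta(i)] = 1.0
        rows.append(r)
        rhs.append(0.0)
    if options.impose_homogeneity:
        for i in range(n):
            r = row()
            for j in range(n):
                r[layout.gamma(i, j)] = 1.0
            rows.append(r)
            rhs.append(0.0)
    if options.impose_symmetry:
        for i in range(n):
            for j in range(i + 1, n):
                r = row()
                r[layout.gamma(i, j)] = 1.0
                r[layout.gamma(j, i)] = -1.0
                rows.append(r)
                rhs.append(0.0)
    for k in pinned_zero:
        r = row()
        r[k] = 1.0
        rows.append(r)
        rhs.append(0.0)
    if not rows:
        return np.eye(P), np.zeros(P)
    A = np.vstack(rows)
    c = np.asarray(rhs)
    R = null_space(A)
    s, *_ = np.linalg.lstsq(A, c, rcond=None)
    return R, s


def _first_stage_arrays(
    data: DemandSystemData,
    corrections: list[ProbitResult] | None,
    resid: ExpenditureResidual | None,
):
    H, n = data.w.shape
    if corrections is None:
        cdf = np.ones((H, n))
        pdf = np.zeros((H, n))
    else:
        cdf = np.column_stack([c.cdf for c in corrections])
        pdf = np.column_stack([c.pdf for c in corrections])
    vhat = np.zeros(H) if resid is None else np.asarray(resid.vhat, float)
    return cdf, pdf, vhat


def _current_b(data: DemandSystemData, beta: np.ndarray, b_mode: str) -> np.ndarray:
    if b_mode == "approx":
        return data.b
    return matsuda_b_index(
        data.w, data.lnp, data.mean_shares, data.base_log_prices, beta=beta, mode="exact"
    )


def predict_shares(
    params: QuaidsParams,
    data: DemandSystemData,
    corrections: list[ProbitResult] | None = None,
    resid: ExpenditureResidual | None = None,
    b: np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic evaluation of the censored share system (H x n)."""
    cdf, pdf, vhat = _first_stage_arrays(data, corrections, resid)
    if b is None:
        b = _current_b(data, params.beta, params.b_mode)
    x = data.lnm - data.ln_a
    latent = (
        params.alpha[None, :]
        + data.lnp @ params.gamma.T
        + np.outer(x, params.beta)
        + np.outer(x**2 / b, params.lambda_)
    )
    pred = cdf * latent + np.outer(vhat, params.theta) + pdf * params.rho[None, :]
    if not np.all(np.isfinite(pred)):
        h, i = np.argwhere(~np.isfinite(pred))[0]
        raise FloatingPointError(
            f"non-finite predicted share for household index {h}, "
            f"category {data.categories[i]!r}"
        )
    return pred


def _design_matrices(data, cdf, pdf, vhat, b, layout):
    """Per-equation regressor matrices X_i (H x k_eq)."""
    H, n = data.w.shape
    x = data.lnm - data.ln_a
    x2b = x**2 / b
    Xs = []
    for i in range(n):
        cols = [cdf[:, i]]
        for j in range(n):
            cols.append(cdf[:, i] * data.lnp[:, j])
        cols.append(cdf[:, i] * x)
        cols.append(cdf[:, i] * x2b)
        if layout.include_theta:
            cols.append(vhat)
        if layout.include_rho:
            cols.append(pdf[:, i])
        Xs.append(np.column_stack(cols))
    return Xs


def _gls_solve(Xs, Y, S, R, s, active):
    """Restricted GLS solve: min Σ_ij S_ij (y_i−X_iψ_i)'(y_j−X_jψ_j) s.t. ψ=Rθ+s."""
    n = len(Xs)
    k = Xs[0].shape[1]
    P = n * k
    M = np.zeros((P, P))
    d = np.zeros(P)
    for i in active:
        for j in active:
            if S[i, j] == 0.0:
                continue
            XtX = Xs[i].T @ Xs[j]
            M[i * k : (i + 1) * k, j * k : (j + 1) * k] = S[i, j] * XtX
            d[i * k : (i + 1) * k] += S[i, j] * (Xs[i].T @ Y[:, j])
    RMR = R.T @ M @ R
    rhs = R.T @ (d - M @ s)
    theta = np.linalg.solve(RMR, rhs)
    psi = R @ theta + s
    return psi, M, RMR


def nlsur_fit(
    data: DemandSystemData,
    corrections: list[ProbitResult] | None = None,
    resid: ExpenditureResidual | None = None,
    options: NlsurOptions | None = None,
) -> tuple[QuaidsParams, FitDiagnostics]:
    """Iterated feasible-GLS estimation of the censored QUAIDS system.

    All n equations are estimated jointly by default (the censoring
    corrections break observed adding-up, so no equation is redundant).
    ``options.drop_equation`` supports the classical drop-one estimation of
    the uncensored system; it requires adding-up restrictions and excludes
    θ/ρ so the dropped equation's parameters are pinned by the restrictions.
    """
    options = options or NlsurOptions()
    H, n = data.w.shape
    include_theta = resid is not None
    include_rho = corrections is not None

    if corrections is None and options.impose_adding_up:
        # uncensored system: observed shares sum to one identically, so the
        # residual covariance is singular and one equation is redundant.
        # Drop one (estimates are invariant to which) and pin its
        # parameters through the adding-up restrictions, extended to θ.
        if options.drop_equation is None:
            options = NlsurOptions(**{**options.__dict__, "drop_equation": n - 1})
        if include_theta and not options.constrain_theta_sum:
            options = NlsurOptions(**{**options.__dict__, "constrain_theta_sum": True})
    if options.drop_equation is not None:
        if not options.impose_adding_up:
            raise ValueError(
                "drop_equation requires adding-up restrictions (they pin the "
                "dropped equation's parameters)"
            )
        if include_theta and not options.constrain_theta_sum:
            options = NlsurOptions(**{**options.__dict__, "constrain_theta_sum": True})
    layout = ParamLayout(n, include_theta, include_rho)
    cdf, pdf, vhat = _first_stage_arrays(data, corrections, resid)
    # pin coefficients whose regressor column is identically zero
    # (pdf of an uncensored category contributes nothing to the fit)
    pinned = []
    if include_rho:
        for i in range(n):
            if np.max(np.abs(pdf[:, i])) == 0.0:
                pinned.append(layout.rho(i))
        if options.drop_equation is not None:
            # the dropped equation's pdf coefficient touches no data
            k = layout.rho(options.drop_equation)
            if k not in pinned:
                pinned.append(k)
    R, s = build_constraints(layout, options, tuple(pinned))

    active = [i for i in range(n) if i != options.drop_equation]
    Y = data.w
    beta = np.zeros(n)
    psi = layout.pack(data.mean_shares, np.zeros((n, n)), beta, np.zeros(n))
    S = np.eye(n)
    sigma = None
    sigma_repaired = False
    trace: list[float] = []
    converged = False
    iterations = 0
    RMR = None

    def residuals(parts):
        params_tmp = QuaidsParams(
            **parts, categories=data.categories, b_mode=options.b_mode,
            include_theta=include_theta, include_rho=include_rho,
        )
        return Y - predict_shares(params_tmp, data, corrections, resid)

    def solve_given_sigma(psi, beta):
        """Inner loop: minimize the GLS criterion for fixed Σ̂ (the b(p)
        aggregator depends on β, so iterate linear solve + b update)."""
        nonlocal RMR, iterations
        for _ in range(options.max_iter):
            iterations += 1
            b = _current_b(data, beta, options.b_mode)
            Xs = _design_matrices(data, cdf, pdf, vhat, b, layout)
            psi_new, M, RMR = _gls_solve(Xs, Y, S, R, s, active)
            parts = layout.unpack(psi_new)
            beta = parts["beta"]
            Ea = residuals(parts)[:, active]
            trace.append(
                float(np.einsum("hi,ij,hj->", Ea, S[np.ix_(active, active)], Ea))
            )
            delta = float(np.max(np.abs(psi_new - psi)))
            psi = psi_new
            if delta < options.tol:
                return psi, beta, Ea, True
        return psi, beta, Ea, False

    def update_weights(Ea):
        nonlocal sigma, sigma_repaired, S
        sigma = (Ea.T @ Ea) / H
        eigvals = np.linalg.eigvalsh(sigma)
        floor = max(1e-9 * eigvals.max(), 1e-12)
        if eigvals.min() < floor:
            sigma = sigma + (floor - min(eigvals.min(), 0.0)) * np.eye(len(active))
            sigma_repaired = True
        S = np.zeros((n, n))
        S[np.ix_(active, active)] = np.linalg.inv(sigma)

    # step 0: nonlinear least squares (Σ̂ = I)
    psi, beta, Ea, converged = solve_given_sigma(psi, beta)
    if options.sigma_iterations is None:
        # iterate Σ̂ and parameters to a joint fixed point
        for _ in range(options.max_iter):
            update_weights(Ea)
            psi_prev = psi
            psi, beta, Ea, converged = solve_given_sigma(psi, beta)
            if converged and float(np.max(np.abs(psi - psi_prev))) < options.tol:
                break
        else:
            converged = False
    else:
        for _ in range(options.sigma_iterations):
            update_weights(Ea)
            psi, beta, Ea, converged = solve_given_sigma(psi, beta)

    if not converged:
        logger.warning("NLSUR inner loop did not converge in %d iterations", options.max_iter)

    # sandwich covariance at convergence: the estimator solves the weighted
    # moment conditions Σ_j S_ij X_i'(y_j − X_jψ_j) = 0, so
    # V = (R'MR)⁻¹ R'GR (R'MR)⁻¹ with G the outer product of per-household
    # scores (robust to heteroskedastic, non-Σ̂ errors)
    parts = layout.unpack(psi)
    b = _current_b(data, parts["beta"], options.b_mode)
    Xs = _design_matrices(data, cdf, pdf, vhat, b, layout)
    Efin = residuals(parts)
    T = Efin @ S.T  # t_ih = Σ_j S_ij e_jh
    k = layout.k_eq
    G = np.zeros((layout.size, layout.size))
    scored = [Xs[i] * T[:, [i]] for i in range(n)]
    for i in active:
        for j in active:
            G[i * k : (i + 1) * k, j * k : (j + 1) * k] = scored[i].T @ scored[j]
    bread = np.linalg.inv(RMR)
    Vfree = bread @ (R.T @ G @ R) @ bread
    vcov = R @ Vfree @ R.T
    vcov = 0.5 * (vcov + vcov.T)
    params = QuaidsParams(
        **parts,
        vcov=vcov,
        restrictions={
            "adding_up": options.impose_adding_up,
            "homogeneity": options.impose_homogeneity,
            "symmetry": options.impose_symmetry,
        },
        categories=data.categories,
        b_mode=options.b_mode,
        include_theta=include_theta,
        include_rho=include_rho,
    )
    E = Y - predict_shares(params, data, corrections, resid)
    sst = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    ssr = np.sum(E**2, axis=0)
    diagnostics = FitDiagnostics(
        r_squared=1.0 - ssr / np.where(sst > 0, sst, np.nan),
        rmse=np.sqrt(ssr / H),
        mae=np.mean(np.abs(E), axis=0),
        iterations=iterations,
        converged=converged,
        objective_trace=trace,
        sigma=sigma,
        sigma_repaired=sigma_repaired,
    )
    return params, diagnostics
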