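import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import ssbdemand as sd
from ssbdemand.first_stage import ProbitResult
from ssbdemand.preprocessing import DemandSystemData
from ssbdemand.quaids import (
    NlsurOptions,
    ParamLayout,
    QuaidsParams,
    _design_matrices,
    _gls_solve,
    build_constraints,
    nlsur_fit,
    predict_shares,
)
from tests.conftest import pack_truth_like


def make_data(seed=0, H=400, n=3, b_unit=False):
    """Hand-built design-matrix bundle with arbitrary shares."""
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.ones(n) * 5, size=H)
    lnp = rng.normal(0.0, 0.3, (H, n))
    lnm = rng.normal(1.5, 0.4, H)
    mean_shares = w.mean(axis=0)
    base = lnp.mean(axis=0)
    from ssbdemand.preprocessing import matsuda_b_index, tornqvist_index

    ln_a = tornqvist_index(w, lnp, mean_shares, base)
    b = np.ones(H) if b_unit else matsuda_b_index(w, lnp, mean_shares, base)
    return DemandSystemData(
        w=w,
        lnp=lnp,
        lnm=lnm,
        ln_a=ln_a,
        b=b,
        mean_shares=mean_shares,
        base_log_prices=base,
        categories=tuple(f"g{i}" for i in range(n)),
        household_ids=np.arange(H),
        covariates=pd.DataFrame({"z": rng.normal(0, 1, H)}),
        income=np.exp(rng.normal(7, 0.5, H)),
        state=np.repeat("S1", H),
        region=np.repeat("R1", H),
    )


def make_params(n=3, seed=0, **overrides):
    rng = np.random.default_rng(seed)
    gamma = rng.normal(0, 0.02, (n, n))
    gamma = 0.5 * (gamma + gamma.T)
    for _ in range(300):
        gamma -= gamma.mean(axis=1, keepdims=True)
        gamma = 0.5 * (gamma + gamma.T)
    beta = rng.normal(0, 0.01, n)
    beta -= beta.mean()
    lam = rng.normal(0, 0.004, n)
    lam -= lam.mean()
    alpha = rng.dirichlet(np.ones(n) * 8)
    fields = dict(
        alpha=alpha,
        gamma=gamma,
        beta=beta,
        lambda_=lam,
        theta=np.zeros(n),
        rho=np.zeros(n),
        categories=tuple(f"g{i}" for i in range(n)),
        b_mode="approx",
    )
    fields.update(overrides)
    return QuaidsParams(**fields)


class TestPredictShares:
    def test_collapses_to_alpha(self):
        data = make_data()
        n = 3
        params = make_params(
            gamma=np.zeros((n, n)), beta=np.zeros(n), lambda_=np.zeros(n)
        )
        pred = predict_shares(params, data)
        np.testing.assert_allclose(pred, np.tile(params.alpha, (data.n_households, 1)))

    def test_cdf_and_pdf_terms(self):
        data = make_data()
        H, n = data.w.shape
        params = make_params(
            gamma=np.zeros((n, n)),
            beta=np.zeros(n),
            lambda_=np.zeros(n),
            rho=np.ones(n),
        )
        phi = 0.39894
        corrections = [
            ProbitResult(
                category=c,
                coefficients=np.zeros(1),
                cdf=np.full(H, 0.5),
                pdf=np.full(H, phi),
                converged=True,
                loglik=0.0,
            )
            for c in data.categories
        ]
        pred = predict_shares(params, data, corrections)
        expected = np.tile(0.5 * params.alpha + phi, (H, 1))
        np.testing.assert_allclose(pred, expected, atol=1e-12)

    def test_matches_independent_reevaluation(self):
        # term-by-term re-evaluation of the share equation, coded separately
        data = make_data(seed=3, H=5)
        params = make_params(seed=4)
        pred = predict_shares(params, data)
        x = data.lnm - data.ln_a
        for h in range(5):
            for i in range(3):
                expected = (
                    params.alpha[i]
                    + sum(params.gamma[i, j] * data.lnp[h, j] for j in range(3))
                    + params.beta[i] * x[h]
                    + params.lambda_[i] / data.b[h] * x[h] ** 2
                )
                assert pred[h, i] == pytest.approx(expected, rel=1e-12)


class TestConstraints:
    def test_fitted_params_satisfy_restrictions(self, small_fit):
        p = small_fit.params
        assert p.restrictions["homogeneity"] and p.restrictions["symmetry"]
        np.testing.assert_allclose(p.gamma.sum(axis=1), 0.0, atol=1e-8)
        np.testing.assert_allclose(p.gamma, p.gamma.T, atol=1e-8)
        np.testing.assert_allclose(p.alpha.sum(), 1.0, atol=1e-8)
        np.testing.assert_allclose(p.beta.sum(), 0.0, atol=1e-8)
        np.testing.assert_allclose(p.lambda_.sum(), 0.0, atol=1e-8)
        np.testing.assert_allclose(p.gamma.sum(axis=0), 0.0, atol=1e-8)

    def test_vcov_symmetric_psd(self, small_fit):
        V = small_fit.params.vcov
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        eig = np.linalg.eigvalsh(V)
        assert eig.min() > -1e-10


class TestGlsSolve:
    def test_matches_dense_kron_oracle(self):
        # restricted GLS vs an independently coded dense stacked solve
        rng = np.random.default_rng(8)
        H, n, k = 60, 3, 4
        Xs = [rng.normal(0, 1, (H, k)) for _ in range(n)]
        Y = rng.normal(0, 1, (H, n))
        A0 = rng.normal(0, 1, (n, n))
        sigma = A0 @ A0.T + n * np.eye(n)
        S = np.linalg.inv(sigma)
        # constrain: sum of first coefficients across equations = 1
        A = np.zeros((1, n * k))
        for i in range(n):
            A[0, i * k] = 1.0
        c = np.array([1.0])
        from scipy.linalg import null_space, sqrtm

        R = null_space(A)
        s, *_ = np.linalg.lstsq(A, c, rcond=None)
        psi, _, _ = _gls_solve(Xs, Y, S, R, s, active=list(range(n)))
        # oracle: whiten with the symmetric square root of S and solve the
        # stacked system by least squares
        W = np.real(sqrtm(S))
        Xbig = np.vstack(
            [np.hstack([W[i, j] * Xs[j] for j in range(n)]) for i in range(n)]
        )
        ybig = np.concatenate([(Y @ W.T)[:, i] for i in range(n)])
        theta, *_ = np.linalg.lstsq(Xbig @ R, ybig - Xbig @ s, rcond=None)
        np.testing.assert_allclose(psi, R @ theta + s, atol=1e-8)


class TestNlsurFit:
    def test_zero_noise_fixed_point(self, zero_noise_fit):
        truth, res = zero_noise_fit
        psi_true = pack_truth_like(res.params, truth)
        assert np.abs(res.params.pack() - psi_true).max() < 1e-6

    def test_first_stage_equals_per_equation_ols(self):
        data = make_data(seed=12)
        opts = NlsurOptions(
            impose_homogeneity=False,
            impose_symmetry=False,
            impose_adding_up=False,
            sigma_iterations=0,
            b_mode="approx",
        )
        params, diag = nlsur_fit(data, None, None, opts)
        layout = params.layout
        Xs = _design_matrices(
            data,
            np.ones_like(data.w),
            np.zeros_like(data.w),
            np.zeros(data.n_households),
            data.b,
            layout,
        )
        for i in range(3):
            coef, *_ = np.linalg.lstsq(Xs[i], data.w[:, i], rcond=None)
            block = params.pack()[i * layout.k_eq : (i + 1) * layout.k_eq]
            np.testing.assert_allclose(block, coef, atol=1e-8)

    def test_estimates_permutation_invariant(self):
        data = make_data(seed=17, H=500)
        opts = NlsurOptions(b_mode="approx")
        p1, _ = nlsur_fit(data, None, None, opts)
        perm = np.array([1, 0, 2])  # keep the auto-dropped last equation fixed
        data2 = replace(
            data,
            w=data.w[:, perm],
            lnp=data.lnp[:, perm],
            mean_shares=data.mean_shares[perm],
            base_log_prices=data.base_log_prices[perm],
            categories=tuple(data.categories[i] for i in perm),
        )
        p2, _ = nlsur_fit(data2, None, None, opts)
        np.testing.assert_allclose(p2.alpha, p1.alpha[perm], atol=1e-8)
        np.testing.assert_allclose(p2.gamma, p1.gamma[np.ix_(perm, perm)], atol=1e-8)
        np.testing.assert_allclose(p2.beta, p1.beta[perm], atol=1e-8)

    def test_price_rescaling_leaves_fitted_shares_unchanged(self):
        # common b and homogeneity: rescaling prices (m fixed) shifts ln a by
        # the same constant; fitted shares identical, intercepts shift
        data = make_data(seed=23, b_unit=True)
        opts = NlsurOptions(b_mode="approx")
        p1, _ = nlsur_fit(data, None, None, opts)
        c = 0.7
        data2 = replace(data, lnp=data.lnp + c, ln_a=data.ln_a + c)
        p2, _ = nlsur_fit(data2, None, None, opts)
        f1 = predict_shares(p1, data)
        f2 = predict_shares(p2, data2)
        np.testing.assert_allclose(f1, f2, atol=1e-8)
        assert np.abs(p1.alpha - p2.alpha).max() > 1e-6

    def test_objective_trace_non_increasing_within_stage(self, small_sim):
        table, _ = small_sim
        res = sd.fit_pipeline(
            table,
            options=NlsurOptions(sigma_iterations=0),
            compute_se=False,
        )
        trace = np.array(res.diagnostics.objective_trace)
        assert np.all(np.diff(trace) <= 1e-8 * (1 + trace[:-1]))

    def test_uncensored_recovery_within_3_se(self, uncensored_truth, uncensored_fit):
        res = uncensored_fit
        psi_true = pack_truth_like(res.params, uncensored_truth)
        se = np.sqrt(np.clip(np.diag(res.params.vcov), 0, None))
        ok = se > 1e-12
        z = np.abs(res.params.pack() - psi_true)[ok] / se[ok]
        assert np.max(z) < 3.0

    def test_diagnostics_shapes(self, small_fit):
        d = small_fit.diagnostics
        assert d.rmse.shape == (4,)
        assert np.all(d.rmse >= 0)
        assert d.converged
        assert np.all(d.mae <= d.rmse + 1e-12)

    def test_drop_equation_requires_adding_up(self):
        data = make_data()
        with pytest.raises(ValueError, match="adding-up"):
            nlsur_fit(
                data,
                None,
                None,
                NlsurOptions(impose_adding_up=False, drop_equation=0),
            )

    def test_serialization_roundtrip(self, small_fit, tmp_path):
        small_fit.params.to_json(tmp_path / "p.json")
        back = QuaidsParams.from_json(tmp_path / "p.json")
        np.testing.assert_allclose(back.pack(), small_fit.params.pack())
        np.testing.assert_allclose(back.vcov, small_fit.params.vcov)
        assert back.restrictions == small_fit.params.restrictions
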