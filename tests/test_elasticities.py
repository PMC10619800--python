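import numpy as np
import pandas as pd
import pytest

import ssbdemand as sd
from ssbdemand.elasticities import (
    EvaluationPoint,
    build_evaluation_point,
    descriptive_tables,
    elasticity_matrix,
    expenditure_elasticity,
    price_elasticity,
    quintile_masks,
    tax_counterfactual,
)
from ssbdemand.quaids import QuaidsParams

from tests.test_quaids import make_params


def random_point(n, seed, cdf_one=False):
    rng = np.random.default_rng(seed)
    shares = rng.dirichlet(np.ones(n) * 6)
    return EvaluationPoint(
        shares=shares,
        lnp=rng.normal(0.0, 0.4, n),
        lnm=float(rng.normal(1.5, 0.3)),
        ln_a=float(rng.normal(0.0, 0.1)),
        b_approx=float(np.exp(rng.normal(0.0, 0.05))),
        cdf=np.ones(n) if cdf_one else rng.uniform(0.2, 0.95, n),
        pop_mean_shares=rng.dirichlet(np.ones(n) * 6),
    )


def oracle_derivatives(params, point, h=1e-6):
    """Independent central-difference derivatives of the latent shares.

    Re-evaluates the share equation from scratch: the Törnqvist deflator
    moves with prices through its weights ½(w_j + w̄_j), and ln b(p) moves
    with β_j (exact mode) or the deviation weights (approximate mode).
    """
    n = params.n
    A = 0.5 * (point.shares + point.pop_mean_shares)
    if params.b_mode == "exact":
        lnb0 = float(point.lnp @ params.beta)
        B = params.beta
    else:
        lnb0 = float(np.log(point.b_approx))
        B = 0.5 * (point.shares - point.pop_mean_shares)

    def latent(lnp, lnm):
        ln_a = point.ln_a + A @ (lnp - point.lnp)
        lnb = lnb0 + B @ (lnp - point.lnp)
        x = lnm - ln_a
        return (
            params.alpha
            + params.gamma @ lnp
            + params.beta * x
            + params.lambda_ * x**2 / np.exp(lnb)
        )

    dP = np.zeros((n, n))
    for j in range(n):
        up, dn = point.lnp.copy(), point.lnp.copy()
        up[j] += h
        dn[j] -= h
        dP[:, j] = (latent(up, point.lnm) - latent(dn, point.lnm)) / (2 * h)
    dM = (latent(point.lnp, point.lnm + h) - latent(point.lnp, point.lnm - h)) / (2 * h)
    return dP, dM


class TestOracleEquivalence:
    @pytest.mark.parametrize("b_mode", ["approx", "exact"])
    def test_analytic_matches_numeric_over_draws(self, b_mode):
        """Analytic price/expenditure elasticities equal the central-difference
        derivatives of the share system across 100 random draws (1e-6)."""
        n_draw = 100
        worst = 0.0
        for seed in range(n_draw):
            n = 3 + seed % 3
            params = make_params(n=n, seed=seed, b_mode=b_mode)
            point = random_point(n, 10_000 + seed)
            dP, dM = oracle_derivatives(params, point)
            for i in range(n):
                for j in range(n):
                    expected = point.cdf[i] * dP[i, j] / point.shares[i] - (i == j)
                    got = price_elasticity(params, point, i, j)
                    err = abs(got - expected) / max(1.0, abs(expected))
                    worst = max(worst, err)
                expected_m = point.cdf[i] * dM[i] / point.shares[i] + 1.0
                got_m = expenditure_elasticity(params, point, i)
                worst = max(worst, abs(got_m - expected_m) / max(1.0, abs(expected_m)))
        assert worst < 1e-6

    def test_package_numeric_mode_agrees(self):
        params = make_params(n=4, seed=1, b_mode="exact")
        point = random_point(4, 2)
        for i in range(4):
            for j in range(4):
                a = price_elasticity(params, point, i, j, mode="analytic")
                m = price_elasticity(params, point, i, j, mode="numeric")
                assert a == pytest.approx(m, abs=1e-7)


class TestLimitingCases:
    def test_cobb_douglas_unitary(self):
        n = 3
        params = make_params(
            n=n,
            gamma=np.zeros((n, n)),
            beta=np.zeros(n),
            lambda_=np.zeros(n),
        )
        point = random_point(n, 3, cdf_one=True)
        for i in range(n):
            for j in range(n):
                e = price_elasticity(params, point, i, j)
                assert e == pytest.approx(-1.0 if i == j else 0.0, abs=1e-12)
            assert expenditure_elasticity(params, point, i) == pytest.approx(1.0)

    def test_lambda_zero_matches_aids_closed_form(self):
        n = 4
        params = make_params(n=n, seed=5, lambda_=np.zeros(n))
        point = random_point(n, 6)
        A = 0.5 * (point.shares + point.pop_mean_shares)
        for i in range(n):
            for j in range(n):
                aids = (
                    point.cdf[i]
                    * (params.gamma[i, j] - params.beta[i] * A[j])
                    / point.shares[i]
                    - (i == j)
                )
                assert price_elasticity(params, point, i, j) == pytest.approx(
                    aids, rel=1e-10
                )
            aids_m = 1.0 + point.cdf[i] * params.beta[i] / point.shares[i]
            assert expenditure_elasticity(params, point, i) == pytest.approx(aids_m)

    def test_engel_and_cournot_aggregation(self):
        # uncensored, restrictions satisfied, evaluation at population shares
        n = 4
        params = make_params(n=n, seed=7)
        rng = np.random.default_rng(8)
        shares = rng.dirichlet(np.ones(n) * 6)
        point = EvaluationPoint(
            shares=shares,
            lnp=rng.normal(0, 0.3, n),
            lnm=1.4,
            ln_a=0.05,
            b_approx=1.02,
            cdf=np.ones(n),
            pop_mean_shares=shares,
        )
        E = np.array(
            [[price_elasticity(params, point, i, j) for j in range(n)] for i in range(n)]
        )
        e_m = np.array([expenditure_elasticity(params, point, i) for i in range(n)])
        assert shares @ e_m == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(shares @ E, -shares, atol=1e-6)

    def test_expenditure_elasticity_term_by_term(self):
        n = 3
        point = random_point(n, 9, cdf_one=True)
        params = make_params(
            n=n, beta=point.shares.copy(), lambda_=np.zeros(n)
        )
        for i in range(n):
            assert expenditure_elasticity(params, point, i) == pytest.approx(2.0)

    def test_share_scaling_drives_own_price_magnitude(self):
        # same parameters, smaller evaluation share -> larger |e_ii + 1|
        n = 3
        params = make_params(n=n, seed=11)
        base = random_point(n, 12)
        small = EvaluationPoint(
            shares=np.array([0.05, 0.45, 0.50]),
            lnp=base.lnp,
            lnm=base.lnm,
            ln_a=base.ln_a,
            b_approx=base.b_approx,
            cdf=base.cdf,
            pop_mean_shares=base.pop_mean_shares,
        )
        big = EvaluationPoint(
            shares=np.array([0.30, 0.30, 0.40]),
            lnp=base.lnp,
            lnm=base.lnm,
            ln_a=base.ln_a,
            b_approx=base.b_approx,
            cdf=base.cdf,
            pop_mean_shares=base.pop_mean_shares,
        )
        e_small = price_elasticity(params, small, 0, 0)
        e_big = price_elasticity(params, big, 0, 0)
        # correct for the Törnqvist-weight difference entering the derivative
        assert abs(e_small + 1.0) > abs(e_big + 1.0) * 0.9

    def test_non_positive_share_rejected(self):
        n = 2
        with pytest.raises(ValueError, match="share"):
            EvaluationPoint(
                shares=np.array([0.0, 1.0]),
                lnp=np.zeros(n),
                lnm=1.0,
                ln_a=0.0,
                b_approx=1.0,
                cdf=np.ones(n),
                pop_mean_shares=np.full(n, 0.5),
            )


class TestElasticityMatrix:
    def test_zero_noise_matrix_matches_truth(self, zero_noise_fit):
        truth, res = zero_noise_fit
        from ssbdemand.synthetic import true_elasticities

        E_true, em_true, _ = true_elasticities(truth, res.data)
        np.testing.assert_allclose(
            res.elasticities.price_elasticities, E_true, atol=1e-4
        )
        np.testing.assert_allclose(
            res.elasticities.expenditure_elasticities, em_true, atol=1e-4
        )

    def test_full_sample_mask_is_identity(self, small_fit):
        res2 = elasticity_matrix(
            small_fit.params,
            small_fit.data,
            small_fit.probits,
            subgroup_mask=np.ones(small_fit.data.n_households, dtype=bool),
        )
        np.testing.assert_allclose(
            res2.price_elasticities, small_fit.elasticities.price_elasticities
        )

    def test_ses_shrink_with_sample_size(self, uncensored_truth):
        from dataclasses import replace

        ses = {}
        for H in (1500, 6000):
            truth = replace(uncensored_truth, n_households=H, seed=77)
            res = sd.fit_pipeline(sd.simulate(truth))
            ses[H] = np.median(res.elasticities.se_price)
        ratio = ses[1500] / ses[6000]
        assert 1.3 < ratio < 3.1  # ~2 expected for a 4x sample

    def test_empty_subgroup_raises(self, small_fit):
        with pytest.raises(ValueError, match="empty"):
            elasticity_matrix(
                small_fit.params,
                small_fit.data,
                small_fit.probits,
                subgroup_mask=np.zeros(small_fit.data.n_households, dtype=bool),
            )


class TestQuintiles:
    def test_masks_partition_sample(self):
        rng = np.random.default_rng(0)
        income = rng.lognormal(7, 1, 1003)
        masks = quintile_masks(income)
        total = np.zeros(1003, dtype=int)
        for m in masks:
            total += m.astype(int)
        assert np.all(total == 1)

    def test_ties_go_to_lower_quintile(self):
        income = np.array([1.0, 1.0, 1.0, 2.0, 3.0])
        masks = quintile_masks(income)
        # the three tied households all fall in the lowest possible group
        assert masks[0].sum() == 3

    def test_constant_income_degenerates_to_full_sample(self, small_fit):
        res = sd.quintile_elasticities(
            small_fit.params,
            small_fit.data,
            small_fit.probits,
            income=np.ones(small_fit.data.n_households),
            quantiles=(1, 5),
            compute_se=False,
        )
        np.testing.assert_allclose(
            res[0].price_elasticities, res[1].price_elasticities
        )
        np.testing.assert_allclose(
            res[0].price_elasticities,
            elasticity_matrix(
                small_fit.params, small_fit.data, small_fit.probits, compute_se=False
            ).price_elasticities,
        )

    def test_pipeline_quintiles_use_subgroup_means(self, small_fit):
        q1, q5 = small_fit.quintile_results
        assert q1.evaluation.subgroup_label == "income quintile 1"
        assert q1.evaluation.n_households + q5.evaluation.n_households < (
            small_fit.data.n_households
        )
        # subgroups genuinely differ in their evaluation point
        assert not np.allclose(q1.evaluation.shares, q5.evaluation.shares)


class TestTaxCounterfactual:
    def test_worked_example(self):
        """Own-price elasticity −1.19 with a 20% price rise gives −23.8%."""
        point = random_point(1, 1, cdf_one=True)
        result = sd.ElasticityResult(
            price_elasticities=np.array([[-1.19]]),
            expenditure_elasticities=np.array([1.0]),
            se_price=None,
            se_expenditure=None,
            evaluation=point,
            categories=("ssb",),
        )
        dq = tax_counterfactual(result, np.array([20.0]))
        assert dq[0] == pytest.approx(-23.8)

    def test_zero_and_identity(self):
        point = random_point(2, 2, cdf_one=True)
        result = sd.ElasticityResult(
            price_elasticities=-np.eye(2),
            expenditure_elasticities=np.ones(2),
            se_price=None,
            se_expenditure=None,
            evaluation=point,
            categories=("a", "b"),
        )
        np.testing.assert_allclose(tax_counterfactual(result, np.zeros(2)), 0.0)
        np.testing.assert_allclose(
            tax_counterfactual(result, np.array([10.0, 5.0])), [-10.0, -5.0]
        )

    def test_linearity(self, small_fit):
        dp = np.array([5.0, 0.0, -3.0, 1.0])
        one = tax_counterfactual(small_fit.elasticities, dp)
        two = tax_counterfactual(small_fit.elasticities, 2 * dp)
        np.testing.assert_allclose(two, 2 * one, rtol=1e-12)


class TestDescriptives:
    def _table(self, toy_config):
        base = dict(state="S01", region="R1", income=10.0, urban=1, log_income=0.0)
        rows = []
        for hid in range(1, 5):
            rows.append(
                dict(household_id=hid, category="other", expenditure=24.0,
                     quantity=2.0, **base)
            )
        rows.append(
            dict(household_id=1, category="soda", expenditure=8.0, quantity=1.0, **base)
        )
        rows.append(
            dict(household_id=1, category="milk", expenditure=8.0, quantity=1.0, **base)
        )
        return sd.PurchaseTable(df=pd.DataFrame(rows), config=toy_config)

    def test_prevalence_and_means(self, toy_config):
        out = descriptive_tables(self._table(toy_config), toy_config)
        row = out["categories"].loc["soda"]
        assert row["prevalence_pct"] == pytest.approx(25.0)
        assert row["mean_expenditure"] == pytest.approx(2.0)
        assert row["conditional_mean_expenditure"] == pytest.approx(8.0)

    def test_all_purchaser_category(self, toy_config):
        out = descriptive_tables(self._table(toy_config), toy_config)
        row = out["categories"].loc["other"]
        assert row["prevalence_pct"] == pytest.approx(100.0)
        assert row["conditional_mean_expenditure"] == pytest.approx(
            row["mean_expenditure"]
        )

    def test_joint_consumption_share(self, toy_config):
        out = descriptive_tables(
            self._table(toy_config), toy_config, ssb_pair=("soda", "milk")
        )
        assert out["joint_consumption_pct"] == pytest.approx(25.0)

    def test_generator_prevalence_matches_targets(self, small_truth, small_sim):
        table, _ = small_sim
        out = descriptive_tables(table, table.config)
        prev = out["categories"]["prevalence_pct"].to_numpy() / 100.0
        np.testing.assert_allclose(prev, small_truth.prevalence_targets, atol=0.02)
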