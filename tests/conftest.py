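"""Shared fixtures: small hand-built tables and session-scoped simulation fits."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import ssbdemand as sd

COVS = ("urban", "log_income", "educ_years", "n_children", "credit_card")


@pytest.fixture()
def toy_config():
    return sd.CategoryConfig(
        categories=("soda", "milk", "other"),
        covariate_columns=("urban", "log_income"),
    )


def _toy_rows():
    # two households in different states/regions
    base = dict(state="S01", region="R1", income=2000.0, urban=1, log_income=7.6)
    rows = [
        dict(household_id=1, category="soda", expenditure=6.0, quantity=3.0, **base),
        dict(household_id=1, category="other", expenditure=4.0, quantity=2.0, **base),
        dict(household_id=2, category="milk", expenditure=2.0, quantity=1.0,
             state="S08", region="R2", income=1000.0, urban=0, log_income=6.9),
        dict(household_id=2, category="other", expenditure=8.0, quantity=4.0,
             state="S08", region="R2", income=1000.0, urban=0, log_income=6.9),
    ]
    return pd.DataFrame(rows)


@pytest.fixture()
def toy_purchases(toy_config):
    return sd.PurchaseTable(df=_toy_rows(), config=toy_config)


@pytest.fixture(scope="session")
def default_truth():
    return sd.make_default_truth(seed=0, n_households=10_000)


@pytest.fixture(scope="session")
def small_truth():
    return sd.make_default_truth(seed=11, n_households=4_000)


@pytest.fixture(scope="session")
def small_sim(small_truth):
    table, internals = sd.simulate(small_truth, return_internals=True)
    return table, internals


@pytest.fixture(scope="session")
def small_fit(small_sim):
    table, _ = small_sim
    return sd.fit_pipeline(table, quintiles=(1, 5))


@pytest.fixture(scope="session")
def uncensored_truth(small_truth):
    return replace(small_truth, censoring=False, seed=21)


@pytest.fixture(scope="session")
def uncensored_fit(uncensored_truth):
    table = sd.simulate(uncensored_truth)
    return sd.fit_pipeline(table)


@pytest.fixture(scope="session")
def zero_noise_fit(small_truth):
    truth = replace(small_truth, censoring=False, noise_scale=0.0, seed=31)
    table = sd.simulate(truth)
    return truth, sd.fit_pipeline(table)


@pytest.fixture(scope="session")
def recovery_report(default_truth):
    return sd.recovery_experiment(default_truth, n_replicates=20, seed=42)


def pack_truth_like(params_fitted, truth):
    """Pack the generating parameters with the fitted layout."""
    t = truth.params
    return params_fitted.layout.pack(t.alpha, t.gamma, t.beta, t.lambda_, t.theta, t.rho)
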