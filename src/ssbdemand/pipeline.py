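"""End-to-end pipeline: purchase diary → elasticity estimates.

Chains unit values → price imputation → system assembly → first-stage
corrections → NLSUR → elasticities, so analysis drivers, tests and
reproduction scripts all run the same code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .elasticities import ElasticityResult, elasticity_matrix, quintile_elasticities
from .first_stage import (
    ExpenditureResidual,
    ProbitResult,
    blundell_robin_residual,
    expenditure_design,
    fit_all_probits,
)
from .io import PurchaseTable
from .preprocessing import (
    DemandSystemData,
    PriceTable,
    assemble_system,
    compute_unit_values,
    impute_prices,
)
from .quaids import FitDiagnostics, NlsurOptions, QuaidsParams, nlsur_fit

__all__ = ["PipelineResult", "fit_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    data: DemandSystemData
    prices: PriceTable
    probits: list[ProbitResult] | None
    resid: ExpenditureResidual | None
    params: QuaidsParams
    diagnostics: FitDiagnostics
    elasticities: ElasticityResult
    quintile_results: list[ElasticityResult] | None = None


def fit_pipeline(
    purchases: PurchaseTable,
    options: NlsurOptions | None = None,
    correct_censoring: bool | None = None,
    correct_endogeneity: bool = True,
    compute_se: bool = True,
    quintiles: tuple[int, ...] | None = None,
    require_reference_purchase: bool = True,
    drop_reference_equation: bool = True,
) -> PipelineResult:
    """Run the full estimation pipeline on a purchase table.

    ``correct_censoring`` defaults to automatic: probit corrections are
    fitted whenever any zero purchases are present.  ``quintiles`` adds
    income-subgroup elasticity evaluations (e.g. ``(1, 5)``).

    Two sample/system choices matter for censored diaries and default on:

    * ``require_reference_purchase`` drops households with no purchase in
      the residual ("other foods") category — for them the diary total is
      not a usable measure of the food budget;
    * ``drop_reference_equation`` excludes the residual category's share
      equation from estimation.  Observed shares sum to one, so that
      equation absorbs the budget of every censored purchase and cannot
      follow the probit-scaled form the censored model assumes; its latent
      parameters are recovered through the adding-up restrictions instead.
    """
    config = purchases.config
    if require_reference_purchase:
        df = purchases.df
        ref = config.reference_category
        buyers = set(
            df.loc[(df["category"] == ref) & (df["expenditure"] > 0), "household_id"]
        )
        n_all = df["household_id"].nunique()
        if len(buyers) < n_all:
            logger.warning(
                "dropped %d of %d households with no %r purchase",
                n_all - len(buyers),
                n_all,
                ref,
            )
            purchases = PurchaseTable(
                df=df[df["household_id"].isin(buyers)].reset_index(drop=True),
                config=config,
            )
    prices = compute_unit_values(purchases)
    geography = purchases.household_frame()[[config.state_column, config.region_column]]
    prices = impute_prices(prices, geography)
    data = assemble_system(purchases, prices, config)

    if correct_censoring is None:
        correct_censoring = bool((data.w == 0).any())
    probits = (
        fit_all_probits(data, allow_uncensored=True) if correct_censoring else None
    )
    resid = (
        blundell_robin_residual(data.lnm, expenditure_design(data))
        if correct_endogeneity
        else None
    )
    if (
        probits is not None
        and drop_reference_equation
        and (options is None or options.drop_equation is None)
    ):
        opts = options or NlsurOptions()
        if opts.impose_adding_up:
            options = NlsurOptions(
                **{
                    **opts.__dict__,
                    "drop_equation": config.category_index(config.reference_category),
                }
            )
        else:
            logger.warning(
                "cannot drop the reference equation without adding-up "
                "restrictions; estimating the full system"
            )
    params, diagnostics = nlsur_fit(data, probits, resid, options)
    elas = elasticity_matrix(params, data, probits, compute_se=compute_se)
    quintile_results = None
    if quintiles:
        quintile_results = quintile_elasticities(
            params, data, probits, quantiles=tuple(quintiles), compute_se=compute_se
        )
    return PipelineResult(
        data=data,
        prices=prices,
        probits=probits,
        resid=resid,
        params=params,
        diagnostics=diagnostics,
        elasticities=elas,
        quintile_results=quintile_results,
    )
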