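# Methods

This note documents the statistical procedure the package implements, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## From diaries to a demand system

The input is a purchase diary: for each household and product category,
total expenditure and quantity acquired over the diary window, plus
geography (state within region), income and sociodemographic covariates.
Prices are not observed; the package builds them in two steps.

**Unit values.** For a household–category cell with purchases, the
quality-adjusted unit value is the expenditure-share-weighted mean of the
per-record unit prices, Σ_k (e_k/Σe) (e_k/q_k), which reduces to
expenditure/quantity for a single record.  A record with positive
expenditure and zero quantity is a data error, not a price.

**Imputation.** Cells without purchases receive the mean observed unit
value in the household's state, falling back to the region mean and then
the national mean; the provenance level is recorded per cell and observed
values are never altered.  The fallback chain guarantees a complete,
strictly positive price matrix even on small samples.  An optional
`state-prices` reading (replace *all* household prices by state means) is
not the default: observed household unit values carry real variation and
are kept.

**Shares and indices.** Shares are w_ih = e_ih / m_h with m_h the
household's total recorded food expenditure; households with m_h ≤ 0 are
dropped and counted.  The Törnqvist index uses the cross-household
geometric-mean price vector p̄ as base,

    ln a(p_h) = Σ_i ½ (w_ih + w̄_i)(ln p_ih − ln p̄_i),

so ln a = 0 when a household faces base prices regardless of its shares.
The b(p) aggregator has two modes: a parameter-free companion index
½ Σ (w_ih − w̄_i)(ln p_ih − ln p̄_i) ("approx"), and the Cobb–Douglas
QUAIDS aggregator ln b = Σ β_i ln p_ih ("exact") recomputed from the
current β inside estimation.  Exact mode is the estimation default; the
choice is recorded in all outputs.

## First stage

One probit per category models the purchase decision 1{w_ih > 0} on an
intercept, the configured covariates, and the household Törnqvist index
(the price control of the decision model).  Fitted Φ are clipped to
[1e-9, 1−1e-9] with a count of clipped values; (quasi-)separation, flagged
by non-convergence or fitted indexes beyond |40|, falls back to a tiny-L2
penalized likelihood with a warning.  A category purchased by every
household in the sample has no selection to correct: in the pipeline it
receives the degenerate correction Φ ≡ 1, φ ≡ 0 and its pdf coefficient is
pinned at zero.

The expenditure control function is the OLS residual v̂ of ln m on an
intercept, the covariates, and log income.  With an intercept present,
mean(v̂) = 0 to machine precision; regressing v̂ on the same design again
returns zero coefficients (idempotence), and rank-deficient designs raise
with the offending columns named.

## Estimation

Given the indices and first-stage quantities, the system

    w_ih = Φ_i(z_h)[α_i + Σ_j γ_ij ln p_jh + β_i x_h + (λ_i/b_h) x_h²]
           + θ_i v̂_h + ρ_i φ_i(z_h) + ξ_ih ,      x_h = ln m_h − ln a_h,

is linear in the parameters for fixed b.  Estimation is feasible GLS:

1. solve the restricted linear GLS problem for the current weights Σ̂⁻¹,
   iterating the solve with the b ↔ β fixed point (exact mode) until the
   largest parameter change is below 1e-6 (at most 100 inner iterations);
2. update Σ̂ from the residuals and repeat step 1.

The default performs **one** Σ̂ update after the initial identity-weighted
stage — the classical two-step FGNLS, which is also the default of the
standard commercial NLSUR implementation.  Fully iterating Σ̂ to a joint
fixed point (`sigma_iterations=None`) is available and appropriate for the
uncensored system, but is *degenerate* for censored share data: observed
shares sum to one identically while the censored model does not add up, so
the smallest eigenvalue of Σ̂ shrinks along the adding-up combination at
each round and the GLS weight on it diverges; the fit then collapses onto
reproducing that single combination (verified in simulation).  A
near-singular Σ̂ is ridge-repaired (eigenvalue floor at 1e-9 of the
largest) with a flag.

**Restrictions.** Adding-up (Σα = 1, Σβ = Σλ = 0, zero γ column sums),
homogeneity (zero γ row sums) and Slutsky symmetry are imposed by default
through a null-space reparameterization of the stacked coefficient vector;
each can be switched off.  Initialization is deterministic: α at mean
shares, everything else at zero.

**The residual category.** Because observed shares add to one, the budget
of every censored purchase reappears in the residual ("other foods")
share.  That equation therefore cannot follow the Φ-scaled form — its
conditional mean contains Σ_{i} (1−Φ_i(z)) w̃_i, which is outside the model
family — and keeping it in the system propagates the misspecification into
every equation through the restrictions and the Σ̂ cross-weighting.  The
default estimator excludes the residual category's equation and recovers
its latent parameters from adding-up (its θ through Σθ = 0, its ρ pinned
at zero); the full-system fit remains one flag away.  A direct consequence
is that the reported per-equation fit for the residual category is poor
(its R² can be negative): the adding-up-implied parameters describe its
*latent* share, while its observed share includes the reallocated censored
budget.  For the same reason the diary of a household that bought nothing
in the residual category does not measure its food budget at all; such
households (~1% in realistic scenarios) are dropped by default, with a
logged count.

For uncensored data the analogous logic applies automatically: one
equation is redundant (Σ̂ is exactly singular), so the last equation is
dropped, Σθ = 0 is added, and estimates are invariant to which equation is
dropped.

**Covariance.** The reported covariance is the heteroskedasticity-robust
sandwich of the weighted moment conditions at convergence,
(R'MR)⁻¹ R'GR (R'MR)⁻¹ with G the outer product of per-household scores.
First-stage estimation uncertainty (probits, expenditure regression) is
not propagated — a deliberate two-step plug-in, matching the delta-method
convention for this estimator; coverage of 95% intervals in the default
synthetic scenario is ≈ 0.97–0.99, i.e. slightly conservative.

## Elasticities

Elasticities are evaluated at a representative point: (sub)sample means of
shares, log prices, log expenditure, ln a, b and Φ.  The price derivative
of the latent share treats the indices as differentiable in prices with
their weights held at the point:

    ∂ln a/∂ln p_j = A_j = ½(w_j + w̄_j),
    ∂ln b/∂ln p_j = B_j = β_j (exact mode) or ½(w_j − w̄_j) (approx mode),
    ∂w̃_i/∂ln p_j = γ_ij − μ_i A_j − (λ_i x²/b) B_j,   μ_i = β_i + 2λ_i x/b.

Then e_ij = Φ̄_i ∂w̃_i/∂ln p_j / w_i − δ_ij and e_i = Φ̄_i μ_i / w_i + 1.
The μ with the quadratic term divided by b is what differentiation of the
estimated system yields and is the default; the plain variant
β_i + 2λ_i x is selectable for comparison.  A central-difference numeric
mode differentiates the same latent function and agrees with the analytic
forms to first order in the step (the test suite verifies 1e-6 relative
agreement over random draws); in the λ = 0 case the formulas reduce to the
standard AIDS closed forms, and in the uncensored restricted case Engel
(Σ w_i e_i = 1) and Cournot (Σ_i w_i e_ij = −w_j) aggregation hold
identically.

Delta-method standard errors use the numeric gradient of each elasticity
with respect to the stacked parameters and the estimator covariance.
Income-quintile elasticities rank households by reported income (ties to
the lower quintile), rebuild the evaluation point from subgroup means, and
reuse the full-sample parameters; subgroup re-estimation is a refit away
but is not the default, since a single parameter set with subgroup
evaluation points is the convention for reporting quintile tables.  Tax
counterfactuals are first order: Δq_i(%) = Σ_j e_ij Δp_j(%).

## Synthetic data generator

The generator emulates the structure of a national budget-survey diary:

* 27 states grouped into 5 regions; log prices are state-level means (SD
  0.12 across states) plus household noise (SD 0.08);
* covariates (urban 84%, log income N(7.6, 0.7), education, children,
  credit card) drive purchase decisions and total food expenditure;
* ln m depends on covariates plus a shock u (SD 0.35) that also loads on
  the share disturbances — the endogeneity the residual inclusion corrects;
* per-category probit censoring with prevalence targets (25%, 15%, 45%,
  99%) and a residual good holding ~71% of the latent budget, the shape of
  the published survey tables (ready-to-drink SSB 24.6%, prepared SSB
  15.8%, milk 41.6%, other foods 99.0%, with "other foods" at ~81% of the
  observed budget);
* share-equation noise SD 0.02 on the first n−1 goods, the last absorbing
  the negative sum so latent shares add to one exactly.

Three choices make the generator *exactly* consistent with the estimating
equations, so that recovery validates the pipeline rather than an
approximation of it: (i) latent shares solve the share equations at the
same Törnqvist index the pipeline computes (a fixed point over the sample,
converged to 1e-13); (ii) the censoring loading ρ_i ζ_i and the
endogeneity loading θ_i v̂/Φ_i(z) are specified so that after discrete
selection the observed-share moments carry exactly ρ_i φ_i(z) and θ_i v̂;
(iii) the budget of a censored purchase is reallocated into the residual
category — the household's food budget is what it is; not buying soda this
week means buying more of everything else — so the censored categories
follow the Shonkwiler–Yen moment exactly.  An alternative
`censored_budget="shrink"` mode removes censored budget from the observed
total instead.  Households whose latent share would be negative (well
under 1% at the defaults; an error above 1%) record no purchase.

Quantities are expenditure/price, so unit values recomputed by the
pipeline reproduce the drawn prices to machine precision for purchased
cells.

**What passing recovery shows — and what it does not.** In the default
scenario (4 goods, 10,000 households, 20 replicates) the pipeline recovers
the generating parameters with median |error|/SE below ~1, own-price
elasticity median absolute bias below 0.01, and interval coverage near
nominal; zero-noise uncensored data is recovered to machine precision.
The generator does not emulate survey weights, diary-week seasonality,
measurement error in quantities, quality substitution within categories,
or misspecified probit link — real-data estimates inherit whatever those
contribute.  The residual-category equation is structurally contaminated
in any complete share system (see Estimation), so its *own* elasticity is
identified only through the adding-up-implied parameters.

## Numerical choices

* NLSUR tolerance 1e-6 on the max absolute parameter change; at most 100
  inner iterations per Σ̂ stage; default one Σ̂ update.
* Φ clipped at 1e-9; probit separation fallback penalty 1e-4·‖b‖².
* Σ̂ eigenvalue floor 1e-9 of the largest eigenvalue (flagged).
* Elasticity delta-method gradients: central differences with relative
  step 1e-6.
* Quintile ranks: minimum rank, ties to the lower group; a constant income
  vector degenerates every quantile to the full sample.
* Degenerate inputs raise early with the offending column/category/row
  named: missing schema columns, unknown category labels, negative
  expenditures, zero-quantity purchases, categories with no observed price,
  single-outcome probits, rank-deficient first-stage designs.

## Known limitations

* Expenditure elasticities here are food-expenditure elasticities, not
  income elasticities; no outside-the-home purchases are modelled.
* No Hicksian (compensated) elasticities or welfare analysis.
* First-stage uncertainty is not propagated into the reported standard
  errors.
* The two-step Φ̂ plug-in treats the probit as correctly specified; a
  misspecified decision model biases the censoring correction.
* Tax counterfactuals are first-order and assume 100% pass-through.
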