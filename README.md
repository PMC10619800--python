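# ssbdemand

Censored demand-system estimation for household budget surveys, built to
measure how purchases of sugar-sweetened beverages (SSBs) respond to price
— the quantity a soda-tax designer needs.  From a week-long purchase diary
(one row per household × product category: expenditure, quantity acquired,
geography, sociodemographics) the package estimates a Quadratic Almost
Ideal Demand System (QUAIDS) and reports own-price, cross-price and
expenditure elasticities, income-quintile elasticities, and first-order
tax counterfactuals.

## The model

Household *h* allocates its food budget *m* across *n* categories.  The
latent share of good *i* is

```
w̃_ih = α_i + Σ_j γ_ij ln p_jh + β_i ln(m_h/a(p)) + (λ_i/b(p)) [ln(m_h/a(p))]²
```

with a(p) the Törnqvist price index and b(p) a Cobb–Douglas aggregator
Π_j p_j^{β_j}.  Two corrections bridge the gap between latent demand and a
one-week diary:

* **Zero purchases** (most households record no SSB purchase in a week):
  a probit of the purchase decision per category gives Φ_i(z_h), φ_i(z_h);
  each share equation is scaled by Φ_i and augmented with ρ_i φ_i
  (Shonkwiler–Yen two-step).
* **Endogenous total food expenditure**: ln m is regressed on household
  characteristics and the residual v̂_h enters each equation with
  coefficient θ_i (Blundell–Robin residual inclusion).

The estimated system,

```
w_ih = Φ_i(z_h)·w̃_ih + θ_i v̂_h + ρ_i φ_i(z_h) + ξ_ih ,
```

is fit by nonlinear seemingly unrelated regression (two-step feasible GLS
with homogeneity, symmetry and adding-up imposed).  Marshallian price
elasticities follow by differentiating the system,

```
e_ij = Φ̄_i (γ_ij − μ_i A_j − (λ_i x²/b) B_j) / w_i − δ_ij ,   μ_i = β_i + 2λ_i x / b ,
```

with A_j, B_j the price derivatives of ln a and ln b, x = ln(m/a), and
δ_ij the Kronecker delta; expenditure elasticities are
e_i = Φ̄_i μ_i / w_i + 1.  Standard errors come from the delta method on
the NLSUR sandwich covariance.

Because observed shares sum to one while the censored model does not add
up, the residual ("other foods") equation cannot follow the probit-scaled
form; by default its equation is excluded from estimation and its latent
parameters are recovered through adding-up (see `docs/methods.md`).

## Worked example

The analysis scripts run the whole pipeline on a synthetic household
budget survey with known parameters (no download needed):

```
python analysis/01_simulate.py --seed 0        # 10,000 households, 4 categories
python analysis/03_fit_demand_system.py --seed 0
python analysis/05_tax_scenarios.py
```

The fit prints, among other things:

```
estimated own-price elasticities:
  ssb_ready       -0.682  (se 0.121)
  ssb_prepared    -0.804  (se 0.168)
  milk            -0.704  (se 0.083)
  other_foods     -0.928  (se 0.024)
```

i.e. a 1% price rise on ready-to-drink SSBs reduces their purchases by
about 0.68% in this simulated population, and the tax scenarios translate
that into policy units:

```
      scenario  ssb_ready  ssb_prepared  milk  other_foods
ssb_ready +20%     -13.64         -3.18  0.96        -0.61
```

— a 20% tax passed fully into prices cuts ready-to-drink SSB purchases by
~13.6% and, the beverages being complements here, prepared-SSB purchases
by ~3.2%.  (With the elasticity of −1.19 estimated on the Brazilian
2017–2018 survey, the same computation gives −23.8%.)
`analysis/06_recovery_experiment.py` checks the estimates against the
generator's truth: over 20 replicates the median absolute bias of the
own-price elasticities is below 0.01 and 95% intervals cover at ~98%.

To run on real data, flatten the survey to a long CSV (columns
`household_id, category, expenditure, quantity`, geography, income and
covariates), describe the categories in a YAML `CategoryConfig`, and call
`ssbdemand.read_purchases` + `ssbdemand.fit_pipeline`.

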