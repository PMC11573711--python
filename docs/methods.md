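# Methods

## Model

`treelim` models annual-mean fractional tree cover on a 0.5° tropical grid
(30°N–30°S) as the product of logistic limitation factors, one per control:

    TC = TC_max · ∏_c f(k_c (X_c − X_{0,c})),    f(x) = 1/(1 + e^{−x})

with five controls *c*:

| control | index X_c | sign |
|---|---|---|
| MAP  | log(MAP + 1/ncells), MAP in mm/yr | + |
| MAT  | mean annual temperature, °C | + |
| SW   | shortwave radiation, W/m² | + |
| S (stress) | weighted power sum of burnt area, rainfall seasonality, heat, wind | − |
| LU (human) | weighted sum of population density, urban, cropland, pasture | − |

`X_{0,c}` is the index value at which the control halves the cover it would
otherwise allow; `k_c` is the logistic steepness, stored as a positive
magnitude with the sign carried by the control so suppressive controls can
be bounded at zero by their priors.  MAT and SW are combined into a single
"energy" factor for display only; they are separate controls in the fit.
The 1/ncells floor in the MAP transform (ncells = number of unmasked
analysis cells after clipping to the band) makes cover vanish with
vanishing rainfall.

Composite indices are

    X_c = Σ_i v_i x_i^{p_i} / Σ_i v_i,   v_1 ≡ 1,

with the factors x_i min–max scaled to [0, 1] first (bounds are data
carried on the `DriverSet`; defaults: warmest-month temperature 10–45 °C,
wind 0–12 m/s, population density 0–5000 km⁻²; fractional drivers pass
through).  Exponents p_i are free only for the stress control — an extra
degree of heat stress matters more at 40 °C than at 25 °C — and fixed to 1
for human pressure.  This structure has exactly 23 free parameters: five
midpoints, five steepnesses, 3+3 non-reference weights, four stress
exponents, and TC_max, σ, P₀.

The scaling of non-fractional factors is a package choice: the
exponential(1) priors on weights and exponents presuppose commensurate
factor scales, and fitted midpoints on [0, 1] indices stay interpretable.

## Rainfall seasonality

Four interchangeable metrics, each in [0, 1], computed from daily or
monthly precipitation climatologies: fractional mean annual dry days
(wet-day threshold 0.1 mm/day, configurable); the dry-day fraction of the
driest month (the month with the largest dry-day fraction — the literal
"fewest dry days" reading is available behind a flag but contradicts the
metric's purpose); minimum monthly precipitation normalised by the monthly
mean; and the vector concentration of monthly totals around the annual
cycle, with month *m* at angle 2π(m−0.5)/12 (any fixed convention leaves
the index rotation-invariant).  Cells with zero annual rain return 0 by
convention for all metrics; the MAP control already eliminates tree cover
there.

## Observation model

Observed cover is zero-inflated logit-normal: a cell is exactly zero with
probability (1 − TC²)(1 − P₀), and otherwise normal on the logit scale
around logit(TC) with standard deviation σ.  Observations and predictions
are clipped into [1e−6, 1 − 1e−6] before the logit so saturated values
(satellite products do report exactly 1.0) stay finite.  The Jacobian of
the logit transform is constant in the parameters and omitted; the
log-likelihood is therefore defined up to an additive data constant, which
leaves the posterior, all impact measures and all likelihood *ratios*
(ensemble weights) unchanged.

## Priors and inference

Priors are deliberately wide: uniform [0, 1] for TC_max and P₀;
exponential(rate 1) for weights, exponents, steepness magnitudes and σ;
normal for each midpoint with **mean and standard deviation both equal to
half the observed range of that control's index** (0.5 for the [0, 1]
composite indices).  That literal mean-equals-half-range prescription is
kept even for the MAP index, whose range does not start at zero; the prior
is wide enough that the choice is immaterial in practice.

Sampling is adaptive random-walk Metropolis–Hastings on transformed
scales — log for positive parameters, logit for unit-interval ones, with
Jacobian corrections — combining two move types per iteration:

* a **component-wise sweep** with per-parameter proposal scales adapted
  during warmup towards 0.44 acceptance (the component-wise optimum);
* **joint moves** (ten per iteration) along the Cholesky factor of the
  empirical posterior covariance, Haario-style, with a global scale
  adapted towards 0.234.  These are what let strongly coupled directions —
  TC_max against the midpoints — mix within short chains; without them
  TC_max is the slowest direction by far.

Adaptation stops at the end of warmup (first half of each chain, default),
so the sampled chain is a valid Markov chain.  The default test-scale
protocol is 4 chains × 2000 iterations with 10 members thinned per chain;
the full-scale protocol (10 chains × 10 000 iterations, members from the
last 5000) is available via the `paper` profile.  Convergence is monitored
with split-R̂ (via ArviZ); a tuning failure (acceptance ≈ 0) raises with
per-chain diagnostics rather than returning garbage.

Fitting uses a uniform random 20% cell split for training with the
remaining 80% held out for calibration checks.  Posteriors fitted to
different datasets or seasonality metrics are combined by bootstrap
resampling with selection probability proportional to each member's
likelihood (softmax of pooled member log-likelihoods), retaining
provenance labels.

### Predictive calibration

Calibration on the held-out split is measured as the fraction of cells
whose observation falls in the central 10–90% posterior-predictive band.
Because the predictive distribution mixes a point mass at zero with a
continuous component, naive membership in a sample-quantile interval is
biased upward whenever the atom straddles the lower quantile (a zero
observation then always counts as covered).  Coverage is therefore
computed through the randomised probability integral transform: the
posterior-mixture predictive CDF is evaluated at each observation, with
the zero atom resolved uniformly at random, and cells with PIT in
[0.10, 0.90] are counted.  Under a well-specified model the expected
fraction is exactly 80% regardless of atom sizes.  Sample-quantile
interval maps remain available for display.

## Impact calculus

All removals follow the weight-zeroing convention: removing a whole
control drops its logistic factor from the product; removing a factor of a
composite control sets its weight to zero, and the weighted-sum
denominator renormalises.  For one posterior member:

* absolute impact |TC_*(i) − TC|; relative impact (TC_*(i) − TC)/TC_*(i),
  which for a whole control collapses to 1 − f (an identity the tests
  check to 1e−12 against brute-force removal);
* limitation 1 − f for positive controls and 1 − f/f(at zero index) for
  suppressive ones, so zero stress means zero limitation;
* sensitivity R = 4 f (1 − f) · TC_*(i): the logistic gradient relative to
  its midpoint maximum, times the cover unconstrained by the control;
* the +1% burnt-area experiment; fire impact without direct human
  influence on tree cover, (TC_*(BA, LU) − TC_*(LU))/TC_*(BA, LU); and the
  same with burnt area replaced per member by a sampled counterfactual
  (no-human) burnt-area field;
* per-unit response curves in 1% factor bins, (TC_* − TC)/(A_bin · TC_*),
  where 1 means the factor excludes cover over exactly its own area;
* the Bhattacharyya coefficient of two impact distributions on a shared
  100-bin histogram of [0, 1] (bin count configurable), reported either as
  overlap or as 1 − overlap; both conventions exist in the literature this
  follows and the package does not privilege one.

Uncertainty always propagates by evaluating each posterior member and
**pairing members across experiments**; experiments are never compared
through independently resampled ensembles.

Two structural consequences of the multiplicative model worth knowing:

1. Because a whole control enters as a separable factor, the *per-cell*
   relative fire impact is unchanged by removing the human control — the
   human factor cancels in the ratio.  Differences between "fire" and
   "fire without humans" arise at the aggregate level, where cells are
   reweighted by their (spatially varying) human limitation, and through
   counterfactual burnt-area substitution.
2. Renormalised factor removal can *decrease* cover: removing a factor
   whose scaled value lies below the weighted mean of the rest
   concentrates the index on the more stressful factors.  Absolute impacts
   are therefore reported as |TC_* − TC|.  The intuition "removing a
   suppressive factor never decreases cover" holds unconditionally only at
   the control level.

## Biome aggregation

Olson classes group into wet forest, dry forest, savanna/grassland,
mediterranean, summergreen forest/woodland, desert and a residual "other";
the grouping table is data and editable.  Table-style summaries are
cos(latitude)-area-weighted sums of absolute impact (cell-area units) and
area-weighted relative impacts (%), computed **per posterior member first
and quantiled across members afterwards** (10/90% by default), so the
bounds express framework uncertainty, not cell-to-cell spread.  Cells are
weighted by full cell area; part-land coastal weighting is not attempted.
An optional deciduous-fraction field multiplies the weights.

## Synthetic study conditions

The generator emulates the statistical structure of the real driver stack,
not its geography: Gaussian white noise smoothed with a periodic Gaussian
kernel (correlation length 3 cells by default) and rank-mapped onto target
marginals (MAP 0–3500 mm/yr, MAT 5–32 °C, SW 150–280 W/m², warmest-month
temperature 20–45 °C, wind 0–12 m/s; burnt area and land-use fractions
skewed towards small values as in real products).  Burnt area and
seasonality share a rank (Spearman) correlation of 0.6, imposed on the
Gaussian copula via r_gauss = 2 sin(πρ/6) so it survives the marginal
transforms.  The default fixture is a 50×50-cell corner of the band with
~80% land (~2000 analysis cells); recovery experiments use a fully
unmasked 50×50 grid (2500 cells) so a 20% training split is exactly 500
cells.  The default true parameter set (TC_max 0.85, σ 0.5, P₀ 0.9,
moderate steepnesses) keeps every control partially limiting somewhere.

What the generator does **not** emulate: sensor artefacts and ranking
biases of satellite cover products, disagreement between burnt-area
products (multi-ensemble input is supported, but members are statistical
perturbations), realistic coastlines or orography, and temporal
variability (fields are climatological means).  Passing tests therefore
demonstrate that the machinery is correct and calibrated under the model's
own assumptions — not that those assumptions hold for any particular
satellite product.

The counterfactual burnt-area generator is a synthetic stand-in for a
reconstructed no-human burnt-area ensemble: it scales observed burnt area
up by a smooth random factor between 1 and a configurable inflation
(humans suppress tropical fire on net), clipped to [0, 1].

## Numerical choices

* Logistic evaluated via `scipy.special.expit` in hot paths; a branch-safe
  fallback elsewhere.
* Quantiles use linear interpolation of order statistics (NumPy default);
  the 10-member example {0.1, …, 1.0} gives 0.19 at the 10% level.
* Bilinear regridding drops masked source neighbours and renormalises the
  remaining weights; a target cell is masked only when all four
  neighbours are; target points outside the source hull clamp to the edge.
* Empty response-curve bins are dropped, not interpolated.
* MCMC determinism: chains are seeded through `SeedSequence.spawn`, so one
  configuration seed fixes the entire ensemble byte-for-byte.
* Scaled-down problem sizes used throughout the tests (500 training cells,
  4 chains × 2000 iterations, 10 recovery replicates) were chosen as the
  smallest configuration at which the recovery and calibration checks are
  statistically meaningful.

## Known limitations

* The sampler is random-walk MH; it is adequate for 23 parameters and the
  test-scale data but no substitute for gradient-based samplers at much
  larger N.
* TC_max is weakly identified when no region is simultaneously
  unconstrained by all controls; its posterior is honest but wide, and its
  mixing relies on the joint covariance moves.
* Relative impacts are undefined (masked) where the unconstrained cover is
  zero.
* The framework addresses the *maintenance* of tree cover: all structure
  is cross-sectional, and nothing here speaks to transient dynamics such
  as deforestation-fire feedbacks.
* Soil covariates are deliberately out of scope.
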