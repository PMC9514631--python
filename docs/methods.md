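# Methods

## Model and estimation

The reconstruction treats the winter population as three classes — calves,
adult females, adult males — and follows each birth cohort through annual
survival. Only survival rates, the first winter's three cohorts, and each
later winter's calf cohort are free parameters (K = 2(Y−1)+3; 33 for the
16-year moose series); all adult cells are deterministic functions of
these via the invariance recursion with the sex-at-birth ratio fixed at
0.5. The 0.5 is not estimable from class counts and is a standard
assumption for moose. The last transition year has no survival parameter:
no survey or telemetry observation after the final winter constrains it.

Both data streams enter one Pearson chi-square objective. Survey cells are
compared on the count scale with the model expectation in the denominator;
telemetry enters as observed versus expected deaths among the collared
sample. The estimator is minimum chi-square, so the objective behaves like
a −2 log-likelihood near the optimum (quadratic, curvature = inverse
variance) without requiring a full distributional model of the
sightability-corrected survey counts. Survey cells for year 1 and for calf
cohorts are included even though each carries a free parameter: those
cells anchor the corresponding parameters to the survey rather than
leaving them identified only through downstream adult cells.

Assumptions worth stating plainly: survival is shared by the sexes within
a year (supported by the telemetry studies' own sex comparisons); the
collared samples are representative of the surveyed population; harvest is
not modelled separately (tribal subsistence harvest in this herd is ~40
animals/yr, well inside survey noise); and class counts derived from ratio
estimates are taken at face value as continuous quantities.

### Optimisation

* Parameters are transformed — survival to logit, abundances to log — so
  the box bounds (S in [0.01, 0.999], abundances in [1, 50,000]) become
  simple and the gradient is well scaled. Any bounded minimiser reaching
  the same minimum is equivalent; L-BFGS-B is used here.
* Bounds rationale: the upper survival bound keeps the telemetry
  denominator n(1−S) positive; the abundance floor of 1 prevents
  degenerate zero cohorts from zeroing a chi-square denominator.
* Initialisation: survival from pooled telemetry (1 − v/n) where a year
  has data, 0.85 otherwise; abundance parameters from the corresponding
  survey cells (column medians fill cells of missing survey years). This
  start is near-feasible, and 10 further starts with multiplicative
  log-normal jitter (σ = 0.2, fixed seed) guard against local minima of
  the 33-dimensional nonconvex objective. On the bundled tables, 80
  independent jittered starts all reach the same optimum (objective
  913.744), so the default 10 restarts are comfortable.
* Convergence: L-BFGS-B with relative-objective tolerance 1e−12, gradient
  tolerance 1e−8, at most 10,000 iterations; the expected-cell floor of
  1e−8 inside the chi-square is unreachable within the bounds and exists
  purely as numeric armour.

## Uncertainty

SEs are square roots of the diagonal of the inverse Hessian of Λ/2,
computed by central finite differences on the natural parameter scale at
the optimum. The half factor makes the chi-square curvature match the
information of a Gaussian log-likelihood, so a pure quadratic
(x−a)²/s yields SE √s exactly. A non-positive-definite Hessian triggers a
warning, a pseudo-inverse fallback, and per-parameter flags; parameters
pinned at a bound are flagged and reported without an SE rather than with
a meaningless one.

Reconstruction models are known to understate uncertainty, so variances
are inflated by the goodness-of-fit scale c = χ²_df/df, computed over the
observed survey cells only (telemetry terms excluded), with
df = A·Y − K = 48 − 33 = 15 for the moose series. The factor multiplies
variances (SE × √c): this is the standard quasi-likelihood reading of the
ratio. It is floored at 1 — inflation is a guard against overconfidence
and is never allowed to shrink intervals; a sub-unit factor is logged.
Confidence intervals for derived quantities (annual totals, per-capita
recruitment R_i = N_{i+1,1}/N_{i,2}) use the delta method through the
Jacobian of the projection recursion, normal quantiles, and a floor at 0.

The per-capita recruitment definition R_i = N_{i+1,1}/N_{i,2} (next
winter's calves per adult female alive this winter) is the one consistent
with a rate series that ends one year before the abundance series does.

## Sensitivity search

The search asks: by what uniform percentage must survival (or recruitment)
over a decline window have been higher for the end-of-window total to
reach 90% of the start-of-window total? Increments accumulate linearly
(factor 1 + 0.001k after k steps of 0.1%); compounding (1.001^k) differs
by under 4% of itself even at the recruitment answer (~2,500 steps), well
inside the reporting precision. The perturbed trajectories are pure
projections from the fitted start-of-window state — the objective is not
re-minimised, because the question concerns the fitted herd, not a
re-estimated one. Per-year survival is capped at 0.999; the criterion is
one-sided (the decline means only the lower side binds). The projection
is monotone in both quantities, so the first k reaching the target is the
minimum.

## Forecasting and projection

The fitted survival and per-capita recruitment series are forecast with an
AR(1)-with-drift model fitted by ordinary least squares on the logit
(survival) and log (recruitment) scales. The transformed scales keep every
forecast — and every simulation draw — inside the rates' natural ranges.
AR(1)+drift is the simplest model that captures both the series' mean
reversion and a possible trend and is exactly reproducible; automatic
model selection over an ARIMA/ETS family would add variance across refits
without adding interpretability, so the model is fixed and the choice is
configurable. Degenerate fits (constant history, |φ| > 1) fall back to a
random walk with the historical innovation SD. Forecast variance
accumulates through the AR recursion, so uncertainty widens with horizon.

The stochastic projection anchors at the reconstructed final-year state,
draws each future year's S and R from the forecast distributions
(normal on the transformed scale), and runs the cohort recursion with
calves_{t+1} = R_t × females_t. Only this parameter (environmental)
stochasticity is simulated by default, matching the forecast-uncertainty
framing; a `demographic=True` flag adds binomial survival and Poisson
births for synthetic studies where within-year demographic noise matters.
Envelopes are empirical 5th/95th percentiles over simulations (1,000 by
default), and λ is each trajectory's geometric-mean annual ratio from the
anchor year to the horizon end, summarised by median and percentiles.

## Synthetic data

The generator projects a known parameter vector through the cohort model
and observes it as the monitoring programme would: each survey cell gets
multiplicative log-normal noise with a chosen CV (mean-unbiased,
σ² = ln(1+CV²)), and each year's telemetry deaths are Binomial(n, 1−S).
The bundled decline scenario is a 16-year truth starting at 8,150 animals
(1,650 calves, 3,200 cows, 3,300 bulls) whose survival sags from ~0.90 to
0.72 mid-series before partly recovering, with recruitment shrinking
roughly threefold — the qualitative shape of the Minnesota series. Its
default observation design is survey CV 10% and 50 collars at risk per
year, the scale of the real programme; collar counts are design inputs,
never simulated.

What the generator does not emulate: the survey's stratified plot
sampling and sightability-correction error structure (the reconstruction
consumes only corrected point counts), spatial structure, and
individual-level covariates. Passing the recovery tests therefore
demonstrates estimator correctness under controlled, well-specified noise
of realistic size — not robustness to design-based error correlation.

The calibration study in the test suite runs 100 replicates of this
scenario (one jittered restart per refit — the data-driven start is close
to truth, so deep restarting is unnecessary), checking that the median
absolute survival error stays under 0.05 and that the inflated 90% CIs
cover true yearly totals in at least 85% of year-replicates. The whole
suite, including that study, runs in about five minutes on one CPU.

## Known limitations

* The female/male split of the fitted adult cohorts is weakly identified
  in later years: both sexes share survival and receive identical calf
  input, so their fitted trajectories converge and the split rests mostly
  on the early survey years. Totals and rates are unaffected; sex-specific
  abundances late in the series should be read with care.
* The count-based annual survival estimator (1 − v/n) matches
  Kaplan-Meier exactly only in years without within-year censoring;
  with censoring it differs in the third decimal. The reconstruction
  objective is defined on the counts, so this does not propagate.
* The inflation factor for the moose fit is large (≈54), reflecting
  survey dispersion far above Pearson scale; intervals are honest about
  that but inherit the normal-approximation shape.
* AR(1) forecasts revert quickly to the series mean; long-horizon medians
  are driven by the historical average rates, and the projection's
  absolute 2030 level is accordingly less certain than its declining
  direction.
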