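# Methods

This note records the statistical models the package implements, the
conventions and numerical choices behind them, and what the synthetic
generators do and do not emulate.

## Bioassay endpoints

Algal growth-inhibition tests are summarized per replicate as the
specific growth rate µ = ln(N_end/N_0)/t in d⁻¹ (t in days; 3 d for the
packaged assays), and percent inhibition I = (µ_c − µ_t)/µ_c × 100
relative to the **solvent control's** mean rate — the carrier-solvent
blank, not the plain control, is the reference wherever one exists,
because treatments share the carrier. I > 100% means the culture
declined below its inoculum. Replicate statistics are reported as
mean ± standard error (sd/√n).

Exposure concentrations are carried on two bases: nominal, and the
geometric mean √(c_start · c_end) of the measured start/end-of-test
concentrations. A non-detect end measurement makes the geometric mean
itself a non-detect; containers preserve that (a `None` plus the
detection limit) and only the dose–response layer substitutes the
detection limit, with a warning, when a numeric value is unavoidable.
The packaged summary tables print geometric means computed from
unrounded measurements, so the loader prefers the printed mean over one
recomputed from rounded start/end values. Measured-to-nominal ratios
are exposed on all three bases (start, end, geometric mean) without
designating one as canonical.

The parent antifoulant is quantified through its methylated
dimethyldithiocarbamate derivative; the back-calculation is the linear
factor p = d × 0.89/0.41. Mass/molar conversion uses
nM = (µg/L)/MW × 1000 with MW 581.56 (parent), 143.21 (Na-DMDC) and
256.34 (2Na-EBDC) g/mol.

Units: all concentrations are normalized to µg/L internally. The
packaged assay tables are stored in µg/L — the values are only
consistent with the µg/L scale (their nanomolar equivalents confirm it)
— while the long-format CSV reader converts rows declaring mg/L by
×1000 and keeps the declared unit for reporting.

## Dose–response

**Continuous (algal growth).** Per-replicate rates of the non-control
treatments are fit by least squares (Gaussian ML) with

  µ(c) = lower + (upper − lower) / (1 + (c/e)^b),

lower fixed at 0 by default: growth is fully suppressed at high dose,
and observed negative rates act as residuals below the floor. The
choice is empirical — with the lower asymptote free, the steep diatom
dataset yields an EC50 outside its own reported confidence interval,
while the fixed floor reproduces every packaged assay's reported EC50;
`lower_free=True` restores the 4-parameter curve (needed when the
quantity of interest is the curve itself, e.g. for the synthetic
generator whose true floor is negative). The reported EC50 is the
*absolute* effect level — the concentration at which the predicted rate
equals half the solvent-control mean — found in closed form from the
fitted parameters, not the curve's inflection `e`. The 95% CI is a
delta-method interval on ln EC50 using the least-squares covariance
σ̂²(JᵀJ)⁻¹; ill-conditioned curvatures (a slope so steep the data carry
no information about it) yield an explicitly unbounded CI rather than a
fabricated finite one. Optimization is Nelder-Mead with five slope
starts (b ∈ {0.5, 1, 2, 4, 8}) and `e` initialized at the concentration
pair bracketing the 50% effect; an EC50 outside the tested range is
flagged as extrapolation.

**Quantal (immobilization).** Binomial ML with logit p(c) = b(ln c −
ln e); EC50 = e, CI from the observed information. Abbott background
correction (p = p₀ + (1−p₀)·logistic, p₀ pooled from the controls) is
off by default — control immobilization in the packaged data is ≤ 10% —
and available as a flag. Controls are excluded from the curve;
`include_solvent_control=True` adds the solvent-control group at its
own measured concentration for carriers with a quantifiable residue.
All-zero or all-full responses are reported as non-identifiable
(`converged=False`) rather than fit.

**NOEC/LOEC.** Two-sided Dunnett many-to-one comparisons of each
treatment against the solvent control (pooled variance,
equal-correlation multivariate-t adjustment; unbalanced replication
enters through per-group n), family-wise α = 0.05. LOEC = lowest
significant concentration; NOEC = highest tested concentration below
the LOEC, or the highest tested concentration (as a lower bound) when
nothing is significant. p-values come from `scipy.stats.dunnett` with a
seeded generator; an independent equicoordinate critical value
(2-D quadrature over the factor-analytic representation, validated
against the multivariate-t quantile of R's mvtnorm and reducing to the
Student-t quantile at one comparison) backs the property tests and the
family-wise-error simulation. Because tables often print only
mean ± SE of triplicates, replicates are reconstructed as the symmetric
triple {m − s√3, m, m + s√3}, which restores both statistics exactly;
group-level significance is unchanged by which concentration basis
labels the groups.

## Species sensitivity distribution

Candidate families and parameterizations (all supported on x > 0):
weibull(shape, scale); gamma(shape, rate); lnorm(meanlog, sdlog);
llogis = logistic in ln x (location, scale); lgumbel = max-Gumbel in
ln x (location, scale); and two 5-parameter mixtures (π, loc₁, scale₁,
loc₂, scale₂) of log-normals and of log-logistics, components ordered
by median. These parameter counts (k = 2 / k = 5) are what the AICc
correction uses.

Fitting is maximum likelihood: closed form (lnorm), profile-score
Newton (gamma, weibull), full Newton with analytic gradient/Hessian and
a Nelder-Mead fallback (llogis, lgumbel), and multi-start Nelder-Mead
for the mixtures (a quantile-split start plus 10 seeded random
restarts, mixing proportion through a logit, component scales floored
at 10⁻³ log units to keep single-point spikes out of the likelihood).
Mixtures that fail to beat their nested single-family counterpart are
retained — they legitimately carry ≈ 0 weight. Goodness of fit is
reported as the one-sample Anderson–Darling, Kolmogorov–Smirnov and
Cramér–von Mises statistics evaluated at the MLE; no GOF p-values are
attached, since the null distributions do not hold with estimated
parameters.

Model averaging uses AICc weights over converged fits. Fitting requires
n ≥ k + 2 per family (so mixtures drop out below n = 7) and averaging
requires at least 6 values. Reports carry both ΔAIC and ΔAICc — with
mixed parameter counts they differ, and published tables are ambiguous
about which they print.

**Hazard concentrations.** Two model-averaged quantile conventions
exist in circulation and can differ by several percent at the 5th
percentile of a 9-point dataset, so both are implemented and the choice
is explicit:

* `weighted_quantile_mean` (default): Σ wᵢ Fᵢ⁻¹(p), the weighted
  arithmetic mean of family quantiles — the convention of the
  widely-used R SSD tooling at the version that produced the reference
  results this package is validated against (0.48 µg/L at p = 0.05 on
  the packaged acute data);
* `weighted_cdf_inversion`: the root of Σ wᵢ Fᵢ(x) = p, solved by
  bracketed bisection on ln x to relative tolerance 10⁻⁹ (0.45 µg/L on
  the same data).

The report always prints the value under the other rule alongside the
chosen one; the divergence is information, not noise.

**Bootstrap CIs.** Both parametric-bootstrap conventions are
implemented, fully seeded (one substream per family from a
`SeedSequence`, so blocks are independent and reproducible):

* `weighted_bounds` (default): each family is bootstrapped against
  itself (draw n values from its fitted parameters, refit the same
  family, take its HC quantile, n_boot times) and the averaged CI
  bounds are the AICc-weight means of per-family percentile bounds.
  This matches the convention behind published model-averaged
  intervals and is the default for that reason.
* `weighted_samples`: iterations are allocated to families by weight
  (largest-remainder rounding); each draws n values from its assigned
  family, refits the candidate set, and recomputes the model-averaged
  HC; the CI is the percentile pair of those averaged values. This
  propagates model-selection uncertainty and has a heavier lower tail;
  in the package's own simulations it is also the better-calibrated
  interval at n = 9 (the acceptance suite verifies ~95% coverage under
  log-normal truth for `weighted_samples`; the naive per-family
  percentile interval undercovers at this sample size).

Families with AICc weight below 10⁻³ are excluded from bootstrap
refitting (weights renormalized): a zero-weight family cannot move the
averaged quantile (removing one changes the HC5 by < 10⁻⁶ relative),
and at n = 9 the +20-vs-+2 AICc penalty gap means a mixture would need
a log-likelihood gain above 9 on a resample to re-enter — while its
5-parameter refit would dominate the runtime of 10,000 iterations.
Refit failures are counted and a failure rate above 20% aborts.

The log-normality check is the Shapiro–Wilk test on ln(values)
(scipy's implementation, which matches R's `shapiro.test`); affine
invariance on the log scale makes the base irrelevant. Plot data uses
Hazen plotting positions (i − 0.5)/n for the empirical points.

## Risk characterization

One value per species enters the SSD: the geometric mean of that
species' comparable acute values (EC50/LC50), singletons passing
through. PNECs are hazard values over an uncertainty factor —
HC5/10 for the probabilistic route (the default factor applied to an
acute-data HC5), minimum chronic NOEC/100 for the conventional route
(the most conservative of the recommended 50–100 range for two trophic
levels); the factor is a settable parameter (1–1000). Risk quotients
are MEC/PNEC with a fixed exceedance threshold of 1, reported to 3
significant figures. Mixture arithmetic is molar (nM): a parent at
concentration C releasing mᵢ molecules of product i contributes
TUᵢ = mᵢ·C/EC50ᵢ; fractions of the parent's toxic unit are evaluated at
the parent's EC50 and are concentration-independent by linearity.
Because the measured degradation product in the packaged exposure data
could derive from either the parent or its own uses, its RQ is computed
against both conventional PNECs (the parent's and the product's own).

## Synthetic data

The generators are pure functions of (parameters, seed) and emulate the
designs the pipeline consumes:

* `simulate_ssd_values` — i.i.d. draws from any candidate family (the
  bootstrap building block). Defaults in examples use the log-normal at
  the packaged acute data's scale (meanlog 2.90, sdlog 2.07 — values
  spanning ~0.7–360 µg/L).
* `simulate_algal_assay` — triplicate 72 h growth curves: true rate
  from a log-logistic whose lower asymptote sits 1.6 d⁻¹ below the
  control rate (deep enough for negative rates at high dose, as real
  assays show), N_start = 10⁵ cells/mL, N_end = N_start·e^{3µ}·ε with
  multiplicative log-normal noise (sdlog = cv, default 0.05 —
  count-like data with near-constant CV, densities always positive).
  The `ec50` argument is defined as the concentration halving the
  control rate — the endpoint the fit reports — so noiseless
  round-trips are exact by construction.
* `simulate_quantal_assay` — binomial counts at
  p(c) = background + (1−background)·logistic(slope·ln(c/ec50)),
  default 20 animals per concentration.

Not emulated: chemical decay kinetics between 0 h and end of test
(measured concentrations are a fixed multiplicative loss factor),
in-vivo-fluorescence-to-density calibration, between-batch variation in
control rates, and non-monotone (hormetic) responses. Tests passing on
synthetic data therefore demonstrate correctness of the estimators
under the stated model, not robustness to those real-data features.

## Numerical choices and degenerate inputs

Convergence tolerances: Nelder-Mead xatol 10⁻¹⁰–10⁻¹², fatol
10⁻¹²–10⁻¹⁴; Newton iterations stop at relative log-likelihood change
10⁻¹²; mixture scale floor 10⁻³ log units; CDF values clipped to
[10⁻¹², 1−10⁻¹²] inside GOF sums. Label switching in mixtures is broken
by ordering components by median. Constant data vectors are rejected
(zero pooled variance in Dunnett, zero log-sd in fits, constant vector
in Shapiro–Wilk). Bootstrap allocation uses largest-remainder rounding
so the per-family counts are deterministic and sum exactly to n_boot.
Report rendering rounds to 2 significant figures with full precision
retained in the machine-readable JSON sidecar; reports embed the
package version, the seed and a configuration hash.

Problem sizes used by the test suite and simulations are chosen at
desk scale: 10,000 bootstrap iterations for reported CIs (the package
floor for publication-grade intervals is 1,000), 10,000-replicate null
simulation for the Dunnett family-wise error, 200 outer replicates at
500 iterations for bootstrap-coverage checks, and 500 replicate assays
for EC50 recovery.

## Known limitations

* No censored-data SSD fitting (non-detect toxicity values), no
  Bayesian SSDs, no chronic SSD (the packaged chronic set, five NOECs,
  is below the n ≥ 6 floor and is carried as data only).
* Delta-method EC50 intervals are symmetric on the log scale and can
  disagree with profile-likelihood intervals on steep curves.
* The continuous EC50 treats the solvent-control mean rate as a known
  constant; its sampling error is not propagated into the CI.
* Mixture MLEs on small samples sit near the boundary of
  identifiability; they are reported with their near-zero weights
  rather than suppressed, and their parameters should not be
  interpreted.
* The conventional-PNEC route takes the minimum NOEC at face value;
  NOECs inherit the design resolution of their assays (a NOEC is bounded
  above by the tested concentration grid).
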