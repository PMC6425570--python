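# Methods

## Demographic accounting

Women aged 15–49 in a country-period are partitioned into six groups:
marital status (married, including cohabiting unions; unmarried) crossed
with contraceptive need (unmet need; using contraception; no need).
Group pregnancies are `Ω^f = w_f · ω_f · 5` (five-year periods; ω is a
per-woman-year risk, so period totals multiply by the period width) and
group abortions `Ψ^f = Ω^f · α_f`, with `α_f ∈ (0,1)` the propensity of
a pregnancy in that group to end in induced abortion. Miscarriages
(spontaneous losses after five weeks, including stillbirths — not given
a separate accounting row) are imputed as one per ten abortions plus one
per five live births, giving the closed identity
`pregnancies = 1.2·births + 1.1·abortions`. Implied live births are
solved at group level as `b^f = (Ω^f − 1.1Ψ^f)/1.2`, which makes
conservation exact within every group; counts are real-valued
expectations because they enter a continuous likelihood. Pregnancies to
no-need women are intended, the rest unintended; the percent of
unintended pregnancies ending in abortion is computed from
unintended-source groups only, in both numerator and denominator, so
the (few) abortions of intended pregnancies never contaminate it.

The published indicator set has fourteen entries: pregnancy, intended-
and unintended-pregnancy, abortion, intended- and unintended-birth and
miscarriage rates (annualized per 1,000 women 15–49), and the
percentages of pregnancies unintended/intended, of pregnancies ending in
abortion, of unintended pregnancies ending in abortion, of births
unintended/intended, and of pregnancies ending in miscarriage.

## Data classification

Both rule engines are total: every datum either classifies to a point /
minimum / maximum / interval observation or is excluded with a recorded
reason (special-population samples), and the audit trail keeps one row
per datum.

**Official abortion statistics** pass five ordered screens — legality,
acknowledged completeness below 90%, an official count below a
survey-of-women estimate (a country-level judgment with an explicit
per-period override), substantial informal-sector provision, and an
expert implausibility review (an input flag, not computed). The first
triggered screen makes the datum a minimum. Counts that include
spontaneous abortions are revised down through the pregnancy identity,
`a = (m − 0.2b)/1.1` (clipped at zero): a previously-point datum becomes
the interval `[a, m]`, a previously-minimum datum keeps its bound with
the revised value. The revision treats the raw count as a genuine upper
bound and expects over-subtraction, because registries capture only a
fraction of all miscarriages.

**Surveys of women** yield point estimates linked to a regional
under-reporting inflation factor when the region contains a country
where a survey coincides with a reliable (point-classified) official
statistic, and minimum estimates otherwise. Non-probability samples,
subgroup breakdowns, AICM multipliers and complication counts, and legal
abortion counts each add a labeled variance component; component
magnitudes are configuration defaults on the transformed scale, since
they represent analyst judgments rather than estimable quantities.
AICM values are complications × multiplier (plus the legal count for the
modified AICM, which is always a minimum), with the complications error
truncated on the right at total complications × multiplier.

**Intention surveys** classify by scope. All-women surveys inform the
all-women percent of births (or pregnancies) unintended and the percent
of marital births intended; ever-married surveys the marital percent;
currently-married surveys the marital percent when recent births are
identifiable and otherwise only a minimum on the all-women percent
unintended (valid when nonmarital births are intended no more often than
marital ones — a property the synthetic worlds respect). Antenatal
samples are recorded against the births denominator. LMUP instruments
yield the interval [unwanted, unwanted + ambivalent]. Microdata without
a marital history yield an interval over the extreme assignments of
post-union births to women no longer in their first union; the lower
end counts ambiguous unintended births as marital and ambiguous intended
ones as nonmarital (and vice versa), so any mixed assignment lies
inside. Surveys without their own sampling error receive the mean
sampling error across surveys in the run (config default 2 percentage
points when none report one). Long recall without microdata flags the
observation for the response-bias model rather than pre-correcting it,
so the extra uncertainty of modeling the bias is carried jointly.

## Hierarchical model

Latent surfaces are `log ω_fct` and `logit α_fct` (log and logit keep
the rates positive and the propensity in (0,1)):

    country baseline (per group)  +  Σ_k β_k x_kct  +  δ_ct

with country baselines drawn around modeling-group means, group means
around world means (country ⊂ modeling group ⊂ world), and δ a
first-order random walk over the six periods, shared across groups
within a country (group-specific temporal wiggles are not identifiable
from the aggregate indicators). Covariates are standardized to mean 0,
SD 1 within the run. Regional inflation factors are
`exp(softplus(ζ_r)) ≥ 1` with ζ pooled across regions; regional
recall-bias intercepts ρ_r shift the expected observed logit of percent
unintended downward for flagged observations. All SD hyperparameters
get half-normal priors; coefficients unit-scale normals; every
hyperparameter lives in the configuration.

Observation likelihoods on the transformed scale: Gaussians with
variance equal to the sum of the datum's components for points
(renormalized truncated normals for right-truncated AICM counts — the
renormalizer must use the same variance as the density, otherwise the
joint density is unbounded in the latent rate); soft bounds
`log Φ((latent − bound)/s)` for minimums, mirrored for maximums, and
differences of Φ for intervals. The softness is
`s_eff = sqrt(s² + Σ components)` with `s = 0.1` by default, so
datum-quality components also widen bounds; hard censoring is the
`s → 0` limit. UNPD live births enter as Gaussian likelihoods with a 2%
coefficient of variation (they are estimates, not truths). A smooth,
scale-free penalty discourages `α > 1/1.1`, the point at which implied
births would go negative.

### Fitting

The log posterior and its gradient are coded analytically (the gradient
is verified against finite differences in the test suite). The
hierarchy is non-centered — deviations are stored as standard-normal
scales times estimated SDs — which removes the funnel geometry that
defeats quasi-Newton methods on centered parametrizations. MAP search
runs L-BFGS along a continuation ladder on the births coefficient of
variation (1.0 → 0.1 → target), walking down the constraint valley
rather than across it, then polishes with damped Newton steps using
finite-difference Hessians of the analytic gradient until the gradient
vanishes (max |∇| < 0.01). The default posterior is the Laplace
approximation at that mode, factorized by eigendecomposition with only
numerically degenerate directions floored, so weakly identified
parameters keep their wide intervals. Preconditioned HMC and adaptive
Metropolis samplers (both started from the Laplace factor, with arviz
R-hat/ESS diagnostics) are available as verification methods; the
Metropolis sampler is checked against quadrature on a one-parameter
soft-bound posterior in the tests. Non-convergence (non-stationary
gradient, floored Hessian directions, weak chain diagnostics) is
flagged in the returned diagnostics, never silently ignored.

Aggregation pools counts draw-by-draw — regional and global rates and
percentages are recomputed from summed counts, never averaged ratios —
so accounting conservation holds for every draw at every level.
Reported indicator tables anchor the point estimate at the MAP-derived
value and recenter the draw quantiles there: sums of group counts are
convex in the latent log rates, so raw Gaussian-draw medians drift
above the mode along weakly identified group-share directions even
when the data pin the total.

### Validation

`validate_holdout` refits without a random subset of observations or
without one country's data and scores held-out point observations on
the transformed scale (bounds have no point prediction to score):
per-datum error, median bias, and empirical coverage of 80%/95%
predictive intervals. Predictions are delta-method: the value at the
mode, with variance from the exact indicator gradient through the
Laplace covariance plus the datum's own error variance. (Naive draw
quantiles are biased here for the same convexity reason as the count
summaries.) Leave-country-out additionally compares that country's
posterior interval widths — measured on the logit scale, where width is
an information measure — against the full-data fit. `select_covariates` ranks
covariate subsets by holdout RMSE plus absolute median bias, breaking
ties toward fewer covariates, and warns on collinear candidates with
the condition number.

## Synthetic worlds

The generator draws truths from the model's own generative process
(world means around the configured defaults with SD 0.3, group means
SD 0.15, country baselines SD 0.2, random-walk innovations SD 0.05),
which is what makes posterior-coverage checks meaningful. Default group
pregnancy risks are 0.20/0.05/0.15 per woman-year for married
unmet-need/using/no-need women and 0.12/0.04/0.01 for unmarried ones —
unmarried no-need women are largely sexually inactive, so nonmarital
births stay predominantly unintended, the ordering the currently-married
bound rule assumes. Abortion propensities default to 0.30/0.40/0.04
(married) and 0.60/0.70/0.10 (unmarried). Regional inflation factors
cycle through 1.25/1.5/2/2.5 and recall biases through 0.1–0.3 logit
units. Exposure: ~1M women per country (lognormal spread 0.3), ~65%
married, fixed within-marriage need shares, 1% growth per period.

Countries cycle deterministically through data regimes (complete
registry, incomplete registry at 70% completeness with a rotating
disclosure mechanism, survey with under-reporting, AICM setting, no
data). Every error component the classifier assigns is actually
realized as noise of the matching magnitude, registries paired with
surveys identify regional inflation factors except in the last region
(whose surveys therefore enter as minimums), spontaneous-inclusive
counts capture only 20–80% of miscarriages, and modified-AICM settings
miss 5–35% of abortions — so minimum datums carry genuine slack below
the truth, as their classification presumes. All randomness flows from
one seed through per-(region, country) `SeedSequence` spawn keys;
enlarging a world never perturbs existing countries. True covariate
effects act on theoretically standardized covariates for the same
reason; the model's empirical standardization differs by O(1/√C),
which is inside posterior uncertainty at the scales used.

What the generator does not emulate: real-country magnitudes or
published estimates, age structure below the 15–49 aggregate,
migration, correlated misreporting across neighboring datums, and
abortion-data series with time-varying completeness. Passing recovery
tests therefore demonstrate internal statistical soundness under the
stated imperfections, not accuracy for any real country.

## Problem sizes and numerical choices

Test and acceptance runs use 4 regions × 5 countries × 6 periods
(~520 parameters, ~270 observations) with 300–400 Laplace draws, the
scale at which a desk machine fits a world in well under a minute;
recovery checks pool ten seeded worlds. Percent observations are
clipped to [0.2, 99.8] before the logit transform; zero counts get a
half-count continuity guard; latent surfaces are clipped at ±40/+30
log units (with gradient masking) purely to keep line searches finite.
Ties in covariate selection break toward fewer covariates; degenerate
holdouts (empty fraction, emptied modeling groups) return empty metrics
or fall back to the hierarchical prior with a warning.

## Known limitations

The Laplace posterior is exact only for Gaussian geometry; its
calibration here is demonstrated empirically by the recovery suite at
the stated scales rather than guaranteed. Individual group-level rates
within the unintended-source block are identified mainly through the
hierarchy (the aggregate indicators constrain their weighted sums), so
their posteriors leap toward the prior as data thin out. Inflation
factors need a within-region survey/registry coincidence; without one
they return their hierarchical prior. The recall-bias model assumes a
common regional intercept rather than survey-specific biases.
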