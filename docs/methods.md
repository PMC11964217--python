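# Methods

## The model

The pipeline estimates a longitudinal mediation chain: a latent
screen-time exposure at wave 1, four sleep facets at wave 2 (three of
which enter a given structural model), and a bifactor depression outcome
at wave 3.  Write η for the structural nodes (screen, SQI, WASD,
chronotype or social jetlag, and the depression factors G, CA, SV), y for
the observed indicators.  The implied moments per group g are

    Sigma_g = Lambda (I − B)^{-1} Psi (I − B)^{-T} Lambda^T + Theta
    mu_g    = nu + Lambda (I − B)^{-1} alpha

and estimation minimises the normal-theory discrepancy

    F_g = ln|Sigma| − ln|S| + tr(S Sigma^{-1}) − p + (x̄ − mu)' Sigma^{-1} (x̄ − mu)

weighted n_g/N across groups, with χ² = Σ_g n_g·F_g at the optimum
(a Wishart (n_g − 1) convention is available via `chisq_mode="wishart"`).

Assumptions worth stating plainly: indicators are treated as continuous
multivariate-normal at fit time even though they are 4- or 6-category
ordinal items; no robust (Satorra–Bentler type) scaling correction is
applied, so χ² and the χ²-derived indices carry the usual second-order
optimism under non-normality while point estimates are essentially
unaffected; missingness is handled by multiple imputation before fitting,
not by FIML.

### Identification and the bifactor

Every latent's (residual) variance is fixed to 1 and all loadings are
free; manifest mediators are promoted to single-indicator nodes (loading
1, zero uniqueness, free residual variance and mean).  The depression
outcome is the 2+1 bifactor: all 21 items load G, items 1–10 additionally
load CA, items 11–21 load SV.  The default keeps G, CA and SV orthogonal
(standard bifactor); a replication mode frees the three factor
covariances, and the structural regressions of CA and SV on the exposure
are carried as explicit fixed-zero paths.  The freed-covariance variant is
prone to empirical underidentification: the fitter detects a near-singular
observed information matrix (condition number above 1e10), reports it in
`FitResult.warnings`, and falls back to pseudo-inverse standard errors
rather than failing silently.  All three pairwise residual covariances
among the mediators are freed by default (`n_mediator_covs=3`); a
two-covariance variant (only the WASD pairs) is exposed because the two
conventions differ by a single parameter and both appear in practice.

### Numerical choices

Start values: loadings from a principal-axis decomposition of the pooled
sample covariance (damped 1/√k for indicators loading k factors),
uniquenesses at half the sample variances, paths at zero, intercepts at
sample means.  Optimisation is L-BFGS-B with analytic gradients
(`ftol` 1e-10, `gtol` 1e-7, memory 30, up to 3 restarts with fresh
curvature memory).  Non-positive-definite implied covariances get a large
penalty value, which the line search treats as infeasible.  The converged
flag is set by optimizer success or a final gradient infinity-norm below
1e-3: bifactor likelihoods routinely end on an essentially flat ridge
(smallest Hessian eigenvalue ~1e-6) where the gradient cannot be driven to
machine zero although parameters are stable to many decimals; genuinely
failed fits report `converged=False` and are excluded from pooling (hard
error if more than 10% of imputations are excluded).  Standard errors come
from the observed information, obtained by central finite differences of
the analytic gradient.  Factor sign indeterminacy is resolved by flipping
any fixed-variance factor whose loading sum is negative (jointly with its
paths, covariances and mean).

Fit indices: RMSEA uses the multigroup convention √G·√(max(χ²−df,0)/(df·N));
CFI and TLI are computed against the per-group independence baseline
(free variances and means), which has a closed form; SRMR includes both
standardized covariance and mean residuals and is group-averaged with
weights n_g/N.  Degrees of freedom count means as moments,
G·p(p+3)/2 minus distinct free parameters.

## Imputation

Chained equations over the raw items and diary fields (never the derived
facets: facets are recomputed inside each completed dataset, so their
deterministic definitions are preserved — the alternative, imputing facets
passively, is deliberately not offered).  Each incomplete variable is
regressed on all others (all-variables-predict-all; gender enters as a 0/1
predictor), coefficients are perturbed by a posterior draw (type-1
matching; σ² from a scaled inverse-χ² draw, β from its normal
distribution, with a tiny ridge against collinear ordinal predictors), and
each missing value is replaced by the observed value of one of the k = 5
donors with nearest predictions.  Donor ties are broken by RNG, not row
order.  Five sweeps over a visit sequence ordered by ascending missingness
fraction; m repetitions on independent `SeedSequence` substreams.  Because
donors are observed values, ordinal items remain in range with no rounding
rule.  Defaults (k = 5, 5 sweeps) follow common chained-equations
practice; the replication profile sets m = 70, while the bundled pipeline
default is m = 5 to keep a full run interactive — m is a single knob.

## Pooling and mediation

Rubin's rules with Barnard–Rubin style df
(m−1)(1 + Ū/((1+1/m)B))²; with zero between-imputation variance the
single-imputation normal interval is reproduced exactly.  χ² statistics
pool via D2: r = (1+1/m)·var(√χ²), F = (d̄/k − ((m+1)/(m−1))·r)/(1+r) on
(k, k^{−3/m}(m−1)(1+1/r)²) df; identical statistics give the χ²/k limit,
and the formula is allowed to go negative (reported with p = 1) rather
than clipped.  Indirect effects are computed within each imputed fit
(delta-method variance b²·var(a) + a²·var(b)) and pooled as derived
parameters; pooling a and b separately and multiplying afterwards is also
available through the pooled path estimates, and the two routes are
compared in the tests.  PM is computed from pooled raw coefficients
(products of pooled standardized coefficients are reported alongside as
point estimates).  PM intervals map the endpoint pairs of the indirect and
total intervals — a non-inferential approximation, flagged as such; a
first-order delta-method interval is available behind
`pm_ci_method="delta"`.  Rows follow the anticipated-effect order
SQI > WASD > chronotype > SJL, and PM is suppressed (flagged) when the
indirect and total effects disagree in sign.

## Invariance testing

Configural, metric (equal loadings; factor variances freed in
non-reference groups) and scalar (plus equal intercepts; latent means
freed) levels, compared by D2-pooled Δχ² at α = 0.05 per rung without
multiplicity correction (mirroring sequential practice).  On rejection, a
greedy partial-invariance search releases one constrained parameter at a
time, bounded at five.  Candidates are scored by exact single-release
refits on the first imputed table — the χ² gain from freeing each
candidate — rather than by raw constrained-gradient magnitudes: the freed
latent mean absorbs much of an intercept violation, which makes individual
gradients point at the wrong parameter, while the refit score localises a
planted violation reliably.  A rung that cannot be refined further (too
few constrained parameters would remain to test) is reported as not
estimable instead of raising.

## The synthetic generator

The generator emulates the three-wave panel the analysis assumes: two
gender groups (2446 boys, 2364 girls), a standard-normal screen factor,
four unit-variance facet latents a·screen + correlated residuals, and
G = Σ b_j·facet_j + c′·screen + residual with Var(G) = 1, plus orthogonal
CA and SV.  Defaults are the published standardized paths (girls' A-paths
0.141/−0.234/0.304/0.227, B-paths 0.142/−0.042/0.037/0.026, c′ 0.015;
boys' 0.052/−0.202/0.261/0.189, 0.085/−0.018/0.014/0.011, c′ 0.021) and
loadings; the social-jetlag residual is coupled to chronotype at r = 0.8,
reproducing the collinearity that forces the primary/secondary model
split.  Ordinal items arise graded-response style, by thresholding
loading-weighted latent responses plus unique noise; thresholds and group
location shifts were calibrated in closed form (the marginal latent
response is standard normal) to the printed summary statistics: screen
item mean ≈ 3.2/6, SQI item means 1.63 (boys) and 2.04 (girls), and a
girls/boys BDI-total ratio ≈ 2.2 via a G mean shift of 0.919.  Item-level
thresholds and residual variances are not published, so they are
calibrated only to those summary statistics — an acknowledged open point.

Diary times invert the facet formulas deterministically (both nightly
durations set to the WASD target, onsets from the midsleep targets,
baseline latency 0.33 h) and add Gaussian jitter (SD 0.25 h) to each
field, so derived facets recover the generating latents at r > 0.9 while
remaining noisy measurements.  Missingness is wave-block (a person missing
at a wave misses all of that wave's items), logistic in the depression
latent score and gender with increasing per-wave offsets; the base rate is
solved by root-finding so the expected longitudinally-complete share
equals the 0.40 target.

What the generator does *not* emulate — and hence what passing tests
cannot show about real data: school-level clustering and municipality
strata, non-normal latent distributions, measurement non-invariance
beyond what a test plants explicitly, item-specific threshold structures,
and missingness that depends on unmeasured causes (MNAR).  Recovery tests
also inherit two deliberate mis-specification echoes of the design: the
fitted primary model omits the generated social-jetlag facet (inflating
the chronotype B-path by roughly its coupling share, ~0.02) and treats
thresholded items as continuous (mild attenuation).  Both effects stay
inside the ±0.05 recovery band at the calibrated size.

## Problem sizes in the test suite

Unit and property tests run on panels of 300–800 per group; the recovery
check uses the full calibrated size (~2400/group, complete data, 20
seeds); invariance calibration runs 100 null and 30 planted seeds at
1000/group with m = 2; the imputation calibration uses a 2000-row MCAR
toy with m = 10.  The acceptance script runs the complete pipeline at
N = 4810 with m = 5.  These sizes are the package's own defaults for a
fast, deterministic suite; all scale linearly if larger designs are
wanted.

## Known limitations

- Plain normal-theory ML only: no robust scaling, no WLSMV/polychoric
  estimation for the ordinal items, no bootstrap intervals.
- PM intervals are approximate by construction (ratio of interval
  endpoints), matching the reporting convention they mirror.
- The partial-invariance search is greedy and bounded; it finds the
  single dominant violation reliably but is not an exhaustive
  specification search.
- The D2 denominator df depends on the exact variant of the formula; the
  implemented variant is stated above and in output metadata, and other
  software may print slightly different reference dfs.
- No multilevel structure (school clustering) in either the generator or
  the models.
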