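# Methods

This note documents the models, the numerical choices, and what the
simulation-based validation does and does not establish.

## The c-time model

Observed baseline-anchored cognition is modelled as

y_ij = g(δ_i + t_ij) − g(δ_i) + ε_ij,  ε_ij ~ N(0, σ²) i.i.d.,

where t_ij are years since each subject's baseline and δ_i is the subject's
latent position on the group timeline. The group curve mixes linear,
quadratic and exponential components,

g(t) = θ₁ t + θ₂ t² + θ₃ (e^{θ₄ t} − 1),

which satisfies g(0) = 0 — required, because baseline subtraction removes
each subject's intercept, and the subject's predicted value must also be
re-anchored at their own position (hence g(δ+t) − g(δ)). c-time is defined
from the baseline visit's position (the one visit every subject shares),
minus the hinge.

### Identifiability

* **Shift vs. curvature.** On a straight line the shifted prediction is
  independent of δ; `fit_shift` refuses a curvature-free curve
  (`UnidentifiableShiftError`). More generally, a subject's position is
  identified only through the curvature their own observation window sees:
  with measurement noise σ = 0.1 z, positions in a locally near-linear
  region of g carry wide uncertainty. This is why the synthetic default
  curve keeps a non-zero quadratic term everywhere (θ = (−0.125, −0.0075,
  −0.03, 0.25)): it implies a mild improvement (~+0.1 z/yr) at very early
  latent times — read as practice-like gains — rolling over into an
  accelerating decline (−0.13 z/yr at the hinge region, −0.23 z/yr five
  years past it). A curve that is flat-then-falling would make early
  positions unidentifiable at realistic noise, and no recovery criterion
  could hold.
* **Translation gauge.** (θ, {δ_i}) and the time-translated
  (θ_c, {δ_i − c}) with θ_c = (θ₁ + 2cθ₂, θ₂, θ₃e^{θ₄c}, θ₄) give identical
  predictions — the family is exactly closed under translation. The gauge is
  pinned by re-centring the mean shift to zero after every shift pass *with
  the compensating curve reparameterisation*, so the pinning step changes no
  prediction and the objective trace stays monotone. Only rank/relative
  positions are interpretable across runs; the anchored zero comes from the
  hinge.
* **Mirror branch.** The alignment objective has a near-mirror local optimum
  in which the curve rises and the position ordering partially reverses
  (the quadratic term is reflection-symmetric; the exponential term breaks
  the symmetry only weakly). `optimize_ctime` therefore multi-starts: a
  pooled fit at δ = 0 plus two declining starting curves, three alternating
  iterations each, keeping the branch with the lowest pooled error before
  continuing. Branches are compared on the pooled objective, never on
  agreement with any truth.

### Optimization

Per-subject shifts: coarse grid (0.5 y default) over the search bounds
(−25, +10 y) followed by bounded scalar minimisation in the best cell
(xatol 1e-6); the previous position is kept when the refit is no better, so
each pass cannot increase the objective. Curve refits: bounded trust-region
least squares over all four parameters pooled across subjects.
Convergence: max parameter change relative to max(1, |θ|) below 1e-4,
defaulting to at most 300 iterations — the alternation crawls along a soft
amplitude/rate valley and typically needs ~100–150 iterations at n = 300;
non-convergence returns a flagged result, not an error. Subjects with fewer
than 3 visits are excluded and counted. `refit_fraction` < 1 warm-starts
the first refit on a random subject subset; all later refits use everyone.

### Hinge scan

Candidates lie on a 0.1-unit grid spanning the observed positions
δ_i + t_ij (a subject can cross the hinge mid-follow-up); candidates need
≥ 10 observations and ≥ 3 subjects on each side. Each candidate h is fit as
a *continuous* piecewise (linear-spline) mixed model along the timeline,

y ~ position + (position − h)₊, random intercept + slope per subject,

whose spline coefficient is the post-minus-pre slope change; subject
baseline anchoring is absorbed exactly by the random intercept. A
discontinuous per-observation group-slope parameterisation was tried first
and rejected: it is misspecified for subjects who cross the hinge
mid-follow-up (no subject-specific continuity point) and mislocated the
break by over a year in simulation. Three further numerical choices:

* fits use ML (not REML) so log-likelihoods are comparable across knots,
  and consecutive candidates warm-start the variance parameters (~6× faster);
* the random-effects structure is chosen once, on a central candidate, and
  held fixed across the scan (random slope when estimable, otherwise random
  intercept only — the slope variance degenerates to zero in some cohorts);
  mixing structures mid-scan would make the likelihood profile incomparable;
* the chosen hinge is the candidate with the highest model log-likelihood
  among those significant after Bonferroni correction across the grid.
  Profile likelihood localises a changepoint; the largest Wald statistic
  does not (it peaks where the contrast is most *precise*, ~0.3 units off
  the true break in simulation). Without the multiplicity correction a
  ~100-candidate scan of null data would nearly always declare some hinge.

If no candidate is significant the scan returns a no-hinge sentinel and
c-times are left unanchored (the caller decides; the CLI reports them as
is).

## SILA

Step 1: each subject's accumulation rate is the OLS slope of value on age
over all their scans (uses all data rather than successive differences);
subjects with < 2 scans are excluded. Rates are binned by the subject's
mean level (default bin width 0.025 DVR, ≥ 5 samples per bin, 10% trimmed
mean for outlier robustness); undersized bins merge into the nearest
neighbour, conserving sample counts. Rates are floored at 1e-4 DVR/yr: mean
sub-threshold rates near zero would stall the backward integration and
break invertibility; true non-accumulators are instead reported as censored.

Step 2: Euler integration of dv/dt = r(v) (linear interpolation between bin
centres, constant extrapolation beyond) forward and backward from
(0, threshold), default step 0.01 y over ±30 y. Euler is exact for constant
rates and within 5e-3 DVR of the analytic logistic solution at this step;
halving dt moves estimated onsets by < 0.01 y in the recovery suite.

Step 3: every observation inside the curve's range gives an onset-age
candidate age_ij − t(v_ij); the default "all-obs" method averages them
("last-obs" is provided for sensitivity). time-to-Aβ+ = baseline age −
onset age, positive meaning already positive. Subjects with all
observations outside the range are censored with the side recorded.

The positivity threshold is either supplied (the packaged default is
0.87 DVR, the value used with this longitudinal PiB pipeline) or fit by a
two-component Gaussian mixture on baseline values; the threshold is the
weighted-density crossing between the component means, requiring the
mixture density to dip strictly between the means — a unimodal sample is
rejected rather than silently thresholded — with mean + 2SD of the lower
component as the fallback when the densities do not cross between means.

## Downstream statistics

* Kurtosis is reported non-excess (normal = 3), matching how the time
  metrics' distributions are usually described (leptokurtic vs normal);
  JB = n/6·(S² + (K−3)²/4) against χ²₂.
* Spearman uses midranks; p by the t approximation, exact permutation
  enumeration for n ≤ 9.
* Cox validation uses the lifelines partial-likelihood fit (Efron ties);
  identical covariate values short-circuit to HR = 1 (no information).
* Longitudinal slope models: value ~ metric + time + metric×time + age +
  sex with subject random intercept and slope, falling back to random
  intercept only, then to OLS — the last because a zero-residual-variance
  (noise-free) dataset is singular for an LME yet still identifies the
  fixed effects exactly; fallbacks are flagged in the result.
* Mediation: a from m ~ x + covariates, b and c′ from y ~ x + m +
  covariates; indirect = a·b, total = a·b + c′ (an algebraic identity for
  OLS on common data), proportion mediated = a·b/(a·b + c′), flagged
  unreliable when indirect and total disagree in sign. Percentile bootstrap
  (default 1000 draws) resamples subjects whole, seeded; bootstrap
  regressions run as numpy least squares on prebuilt design matrices for
  speed, with point estimates cross-checked against statsmodels OLS in the
  tests.
* Path model: variables are z-standardized and each endogenous node is
  regressed on its DAG parents plus the adjustment covariates
  (DAG-ordered least squares — identical to covariance fitting for
  recursive models with complete data, and directly oracle-checkable);
  indirect effects are coefficient products along declared paths with
  seeded percentile bootstrap CIs.

## Synthetic cohorts: what they emulate, and what they don't

Defaults mirror the source study's design: cognitive panels of 4–10 visits
over 1.7–11.6 years (annual-ish visits with uniform timing jitter, first
visit at t = 0), amyloid panels of 3–5 scans over 4.2–9.7 years, baseline
ages ~N(71.5, 8²) and N(72.8, 5.9²). True shifts default to
Uniform(−15, 5) years — a stress-test choice, since no empirical shift
distribution is available for the restricted cohort. Amyloid trajectories
are four-parameter logistics in age (floor 0.70, ceiling 1.40 DVR,
rate 0.25/yr) whose midpoint is placed so the noise-free curve crosses the
threshold exactly at the recorded onset age; baseline scan age defaults to
onset + Uniform(−12, 4) years so a realistic fraction of subjects straddle
the threshold during follow-up, as in an accumulator-enriched PET sample.
Practice effects are a one-time additive bump from visit 2 onward — the
simplest retest-learning structure that stresses curvature estimation.
Noise is i.i.d. Gaussian per visit, matching the least-squares objective's
implicit error model.

Not emulated: within-subject autocorrelation, item-level test structure,
informative dropout (censoring is administrative only), scanner or batch
effects, and floor/ceiling effects in the composite. Passing the recovery
suite therefore shows the estimators invert their own generative model at
realistic noise and design — it does not certify performance under model
misspecification on real data.

## Validation sizes and seeds

The recovery suite uses 300 cognitive subjects (noise 0.1 z), 150 amyloid
subjects (noise 0.02 DVR), 100-subject hinge cohorts (5 visits over 5 y,
noise 0.05), 2000-subject structural tables, 500-subject Cox recovery with
200 null replicates of 200 subjects each, and 2000 Jarque–Bera replicates
at n = 500 — sizes chosen so each check is statistically meaningful while
the whole suite runs in minutes on one CPU. All randomness flows from
explicit integer seeds; rerunning any generator, bootstrap, or the
acceptance script with the same seed reproduces results bit-identically.

## Known limitations

* c-time point estimates carry no uncertainty intervals (matching the
  method's usual use); positions of stable subjects far from the curvature
  region are weakly identified and shrink toward the cohort centre.
* The hinge is a grid point, so its resolution is the scan step (0.1).
* SILA extrapolates the rate curve as constant beyond the observed level
  range; onset estimates for subjects far outside the sampled range inherit
  that extrapolation.
* The alternating optimiser guarantees a non-increasing objective, not a
  global optimum; the multi-start pilot makes the mirror branch rare but
  cannot exclude other local optima.
* The path model assumes a recursive (acyclic) structure with complete
  cases; there is no latent-variable measurement model.
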