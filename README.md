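# adtime

Latent disease-time estimation for preclinical Alzheimer's disease from
longitudinal cognition and amyloid PET, with the downstream validation,
mediation and path-analysis statistics, and seeded synthetic cohorts with
known ground truth.

## The problem

In cognitively normal older adults, amyloid accumulates and cognition
declines along strongly non-linear trajectories whose onset age and pace
differ across people. Two per-subject chronicity scales summarise where an
individual sits on these processes:

* **c-time** — a subject's signed distance (in years) from a group-level
  "hinge point" of cognitive decline. Each subject's baseline-anchored
  cognitive composite trajectory (e.g. PACC-5 z-scores) is slid along a
  shared group curve

  `g(t) = θ₁·t + θ₂·t² + θ₃·(exp(θ₄·t) − 1)`,  with `g(0) = 0`,

  to the latent position δ minimising `Σⱼ (y_ij − [g(δ + t_ij) − g(δ)])²`.
  The group curve is then refit at the new positions and the two steps
  alternate until θ converges (the pooled squared error is non-increasing by
  construction). A piecewise linear mixed model scanned every 0.1 unit along
  the timeline locates the hinge — the point where cognitive slopes before
  and after differ significantly — which is subtracted to define c-time zero.
  Higher (positive) c-time = steeper decline; negative = stability or
  practice-effect improvement.

* **time-to-Aβ+** — signed years between a subject's baseline age and their
  estimated age of crossing the amyloid positivity threshold (0.87 DVR,
  from a two-component Gaussian mixture at baseline), positive = already
  positive. The SILA (sampled iterative local approximation) algorithm
  (1) samples each subject's within-person accumulation rate dv/dt against
  their mean level v, (2) integrates the binned rate field `dv/dt = r(v)`
  (Euler) into a level-versus-duration curve anchored so duration 0 is the
  threshold, and (3) solves that curve for each observed value and subtracts
  the resulting duration from the age at observation.

The downstream layer reproduces the usual inferential battery: moment
skewness/kurtosis with Jarque–Bera, Spearman/Kruskal–Wallis/age-adjusted
regressions, Cox proportional-hazards validation against conversion,
linear mixed models for longitudinal biomarker slopes, single-mediator
mediation with percent mediated `a·b/(a·b + c′)` and percentile bootstrap,
and a recursive path model on standardized variables.

Because the cohorts such models are fit to are typically request-only, the
package ships a first-class synthetic-cohort module (`adtime.simulate`)
whose generators invert the estimators' models and record the ground truth
(true shifts, onset ages, structural coefficients), so every estimator is
validated by parameter recovery.

## Worked example

```python
import numpy as np
from adtime import (gen_cognitive_cohort, gen_amyloid_cohort, CTimeAligner,
                    SilaModel, spearman, dist_stats)

cog, cog_truth = gen_cognitive_cohort(120, noise_sd=0.1, seed=11)
aligner = CTimeAligner(hinge_step=0.1).fit(cog)
print(f"converged in {aligner.n_iter_} iterations, hinge at {aligner.hinge_:.1f}")

# amyloid scans for the same subjects; onset loosely coupled to cognition
offsets = np.clip(0.5 * cog_truth.subjects["delta"].to_numpy()
                  + np.random.default_rng(11).normal(-3, 3, 120), -12, 4)
amy, _ = gen_amyloid_cohort(120, noise_sd=0.02, seed=12, id_prefix="s",
                            baseline_offset_dist=offsets)
est = SilaModel(threshold=0.87).fit(amy).predict(amy)

merged = aligner.ctimes_.merge(est[~est["censored"]], on="subject_id")
rho, p = spearman(merged["ctime"], merged["time_to_positive"])
print(f"Spearman(c-time, time-to-Ab+) = {rho:.2f} (p = {p:.2g})")
ds = dist_stats(aligner.ctimes_["ctime"])
print(f"c-time: mean {aligner.ctimes_['ctime'].mean():.1f} y, "
      f"skewness {ds.skewness:.2f}, kurtosis {ds.kurtosis:.2f}")
```

prints

```
converged in 67 iterations, hinge at 12.7
Spearman(c-time, time-to-Ab+) = 0.69 (p = 4.8e-18)
c-time: mean -12.7 y, skewness 0.14, kurtosis 1.99
```

The hinge sits 12.7 years past the cohort's mean position, so anchored
c-time averages −12.7 years: most simulated subjects are well before the
slope break, as expected in a clinically normal cohort. The two latent
time scales correlate positively because the simulated amyloid onsets were
coupled to the cognitive shifts.

## Command line

```bash
adtime simulate --seed 1 --out run/     # cohorts + ground truth tables
adtime ctime    --seed 1 --out run/     # alignment, hinge scan, c-times
adtime sila     --seed 1 --out run/     # rate curve, duration curve, onsets
adtime stats    --seed 1 --out run/     # correlations, Cox, mediation, paths
adtime full     --config cfg.yaml --seed 1 --out run/   # all of the above
```

All tables are comma-delimited with headers; every stage writes a manifest
with the config hash and seed, refuses to overwrite without `--force`, and
reruns byte-identically for the same config and seed.

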