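# Methods

## Disease-state model

Patients are observed at clinic visits at irregular times; at each visit the
CDAI (tender joint count 0–28 + swollen joint count 0–28 + patient global
0–10 + physician global 0–10, total 0–76) classifies disease activity.
Cutoffs are inclusive on the lower side throughout: remission ≤ 2.8, low
(2.8, 10], moderate (10, 22], severe > 22. Three nested schemes are exposed:
`four_state` keeps remission separate, `three_state` folds remission into low
(the scheme the transition analyses use), `two_state` folds moderate and
severe together (the scheme the binary regressions use). Coarsening commutes
with classification, which is tested on boundary-dense grids. The globals are
treated as continuous 0–10 (registries record fractional means), and a visit
lacking both a CDAI score and a complete component set is excluded with
counts logged.

The substantive model is first-order Markov: the state at a visit depends on
the past only through the state at the previous visit. Three estimator
families share this assumption but differ in how they treat time:

1. **Empirical per-visit matrix.** Transition counts n_ij over
   consecutive-visit pairs are the sufficient statistic; the MLE is the row
   proportion. "Per visit" means the matrix is conditioned on the cohort's
   realized visit-interval distribution — matrices from cohorts with
   different schedules are not directly comparable, which motivates (2).
   Prior states never observed give NaN rows (never silent zeros); an
   optional Jeffreys (+½) smoother exists for tiny simulations.

2. **Continuous-time multi-state model.** A time-homogeneous CTMC with
   generator Q (off-diagonals ≥ 0, rows sum to 0) gives
   P(t) = exp(Qt), so each visit pair contributes
   log [P(Δt)]_{prior,current} to the panel log-likelihood regardless of its
   interval. Q is estimated in log-intensity space (positivity by
   construction) with L-BFGS-B from 3 starting points (a fixed default start
   plus seeded jitter, guarding against local optima); all six off-diagonal
   intensities are free, since registry data show direct low→severe moves
   between visits (a tridiagonal restriction is not imposed). The
   covariance is the inverse observed information from a numerical Hessian.
   The fitted Q yields interval-standardized matrices — P(6 months) is the
   headline — and mean sojourn times −1/q_ii with delta-method SEs and
   log-scale Wald CIs (a delta-vs-bootstrap agreement test backs the
   approximation). Intervals are rounded to a 0.01-month grid before
   aggregation: the likelihood is smooth in t, the perturbation is far below
   measurement resolution, and evaluation cost drops from O(pairs) to
   O(unique intervals) via one eigendecomposition per objective call (with
   an `expm` fallback for ill-conditioned generators). Fits with fewer
   observations than free intensities are rejected; rates driven to ~0 are
   flagged as unidentified rather than reported.

3. **Markov logistic regression.** Current state regressed on prior state,
   interval bin, and covariate categories; multinomial logit (base category:
   low) for three states, binary logit for two. Fitting is Newton from a
   zero start (deterministic) via statsmodels, with the design matrix,
   contrasts, and the patient-clustered sandwich
   H⁻¹(Σ_c s_c s_cᵀ)H⁻¹ · G/(G−1) built in-package. The small-sample factor
   G/(G−1) is on by default (G = patients; the no-correction variant is a
   flag); note statsmodels' own `cov_type="cluster"` additionally applies
   (n−1)/(n−k), a difference the cross-check test accounts for explicitly.
   Odds ratios are Wald contrasts exp(c′β ± 1.96√(c′Vc)); for a covariate
   interacted with prior state, the effect within the moderate/severe
   stratum is the main + interaction contrast. Population-level transition
   matrices come from marginal standardization (set prior = i on every
   observed covariate row, predict, average); at-means prediction is not
   used because it answers a different (covariate-profile-specific)
   question. Age enters as a main effect only in the headline model, since
   its interaction with prior state is not supported by the screening fits;
   an interacted variant is available through `ModelSpec`.

Two sojourn constructions are reported side by side, because the discrete
and continuous routes genuinely differ: the CTMC mean −1/q_ii (default,
carries an SE), and the discrete-geometric mean interval/(1 − π_ii) from the
per-visit matrix (no SE; depends on the realized visit spacing). Absorbing
states yield flagged infinite sojourns, not errors.

## Cohorts, intervals, covariates

- Visit times are months from each patient's first visit; date columns
  convert at 30.4375 days/month (365.25/12), a deterministic documented rule.
- The **regular-visit sub-cohort** keeps a patient only if *every*
  inter-visit gap is in [3, 9] months. The full-cohort analysis keeps all
  consecutive pairs whatever the gap; missed states are never interpolated.
- Interval bins: fixed 1-month bins 3–4 … 8–9 (half-open, last closed, so
  9.0 falls in 8–9) for the regular sub-cohort; empirical quintile bins for
  the full cohort whose gaps exceed 9 months.
- Covariates for a transition are taken at the **prior** visit — the model
  predicts the current state from the state (and conditions) being departed;
  `covariate_timing="current"` is available for sensitivity. Categories:
  calendar year (2001–2004, then 2-year windows to 2013–2014), disease
  duration (0–3, 3–10, >10 years), age (<50, 50–64, ≥65), all
  lower-inclusive (50 → 50–64).
- Two selectors exist for "incident moderate" patients: the transition rule
  (first remission/low → moderate step defines entry) and first-visit
  moderate status; the transition rule is the primary definition.

## Synthetic registry generator

The generator produces cohorts with known truth under the study conditions
the estimators target:

- **Interval laws.** Regular: gamma truncated to [3, 9] months with
  truncated-law mean 5.3 and SD 1.5 (shape/scale solved from incomplete-gamma
  moment identities at config time). Full: lognormal with arithmetic mean
  5.4 and SD 3.1, floored at 0.5 months — long-tailed, so some gaps exceed
  9 months, exercising the quintile path.
- **Visits per patient**: minimum 2 plus a Poisson excess, defaulting to
  mean 8.4 (≈ published visits/patient); recovery studies use mean 6.
- **State dynamics.** Discrete mode draws each next state from a per-visit
  matrix (default: the published full-cohort matrix) with covariate effects
  added on the multinomial log-odds; the covariate acts at the visit being
  departed, matching the regression's prior-visit attachment. CTMC mode
  simulates the exact jump chain (default generator: exit rates = reciprocal
  published sojourn means, jump distribution = published off-diagonal
  proportions) and reads states at visit times; the full jump path is
  returned as ground truth. Covariate effects are a discrete-mode feature;
  proportional-intensity effects are out of scope for the headline pipeline,
  which follows the covariates-in-the-regression design.
- **Initial states** follow the published first-visit CDAI mix
  (0.471/0.283/0.246).
- **CDAI decomposition** draws a score uniformly inside the latent state's
  interval (severe capped at 50 by default — scale maximum 76 is clinically
  implausible as a routine draw) and splits it into integer joint counts and
  fractional globals summing exactly to the score, so classification
  round-trips to the latent state by construction.
- **Covariates** advance deterministically with time from sampled baselines
  (enrollment year uniform 2001.75–2013.5; age normal 58 ± 13.4 clipped to
  18–95; baseline duration exponential mean 9 years) and are independent
  across patients — a simplification: real registries correlate age,
  duration, and calendar time, and visit schedules may depend on disease
  state, which the generator (like the model) assumes they do not. Passing
  recovery tests therefore demonstrates estimator correctness under the
  model, not robustness to informative observation.
- **Reproducibility.** The global seed expands to per-patient substreams via
  `SeedSequence((seed, patient_index))`, so a patient's schedule and
  covariates are invariant to cohort size; state evolution and CDAI
  decomposition use a separate cohort-level substream keyed at
  `(seed, 2**31)`.

## Numerical choices

- Newton logit fits: zero start, tolerance 1e-10, max 200 iterations; a fit
  whose score exceeds 1e-6 (scaled) raises. Coefficients beyond ±15 trigger
  a separation warning naming the terms. Rank-deficient designs raise with
  the aliased columns identified by pivoted QR.
- CTMC fits: L-BFGS-B bounds on log-intensities [−20, 5] (rates from ~2e-9
  to ~150/month), ftol 1e-12; convergence is declared on a scaled gradient
  norm below 1e-6.
- Wald quantile 1.959964 everywhere; probabilities are reported to 2
  decimals and ORs to 3 in CSV reports, with full precision in JSON
  sidecars; report writes are atomic and embed the config hash.
- P(t) rows renormalize within 1e-10 and entries are clipped at −1e-12;
  larger violations raise.

## Validation scale

Test and recovery problem sizes are chosen so sampling error is well below
the effects being recovered while a full run stays laptop-friendly: matrix
recovery uses 20,000 patients × mean 6 visits (~100k transitions; binomial
3 SE ≈ 0.008 on the moderate row), sojourn recovery 10,000 patients (CI
half-widths ≈ 1–2% of the means), OR recovery 20,000 patients × mean 8.4
visits for point estimates, and the coverage study 100 replicates × 1,500
patients — large enough per replicate for Wald intervals to be near nominal,
small enough for 100 refits. Property tests run at 10⁴–10⁵ draws.

## Known limitations

- Time-homogeneity: Q and π are constant over calendar time and within
  patient; secular trends enter only through regression covariates.
- First-order Markov: no dependence on deeper history.
- Non-informative observation times are assumed everywhere.
- The two-state generator's covariate effects are on per-visit log-odds;
  recovering them requires the regression's interval adjustment to absorb
  schedule variation, which the recovery studies confirm it does.
- Misclassification of states (CDAI measurement error) is not modelled.
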