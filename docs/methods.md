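# Methods

## Model and assumptions

`clinclock` estimates biological age (BA) under a Gompertz view of adult
mortality: the log all-cause hazard rises approximately linearly with age,
so the hazard doubles every MRDT = ln 2 / b years, where b is the per-year
log-hazard slope. If a subject's predicted hazard is r times the hazard
expected for their chronological age (CA) and sex, they are treated as
Δage = ln(r)/ln(2) · MRDT years biologically older, and BA = CA + Δage.
This presumes (i) proportional hazards within sex, (ii) an approximately
log-linear age gradient over the cohort's age range, and (iii) that the
training cohort defines the reference hazard. All mortality models are
sex-stratified; feature normalization is pooled across sexes by default
(component structure is estimated cohort-wide, risk models per sex), with a
`sex_specific` switch.

The reference point for r is a deliberate modelling choice, the single most
consequential one in the pipeline: we define
ln r = (η − η̄_sex) − b_sex·(CA − C̄A_sex), where η is the PC-clock linear
predictor and η̄, C̄A are training means per sex. This makes the
training-cohort mean Δage exactly zero per sex and makes the linear-collapse
constant C₀ a closed form. Alternatives (e.g. referencing the baseline
hazard at fixed covariates) shift every Δage by a constant and leave all
rankings, survival stratifications and rate contrasts unchanged.

## Pipeline

1. **Normalization.** z-scores from training mean/sd, or robust
   median/MAD statistics over a designated healthy reference subset (used
   for sparse clinical clocks). Features such as ordinal smoking status or
   morbidity indices can be exempted and enter on their native scale.
   Zero-variance features are an error, not silently dropped.
2. **SVD.** Correlation-mode PCA (z-score then SVD). Singular-vector signs
   are fixed so each component's largest-magnitude loading is positive,
   making serialized models reproducible. Retained count m = smallest m
   whose cumulative variance fraction reaches the target (default 0.99).
3. **Cox fits.** lifelines `CoxPHFitter` (Efron tie handling) for the null
   (CA-only) and PC clocks, per sex. The null model's slope must be
   positive; MRDT outside [2, 30] years triggers a sanity warning.
4. **Stability selection.** For each penalty mixing α ∈ {1, 0.75, 0.5} the
   elastic-net Cox coefficient path is fit once on the full data
   (scikit-survival coxnet; CA force-included via a zero penalty factor).
   Each of n iterations (default 100; a reduced 25-iteration protocol is
   used in the test suite and acceptance script purely for speed — the
   behaviour is identical) reshuffles the 10-fold assignment and accumulates
   the Verweij–Van Houwelingen cross-validated partial-likelihood deviance
   along the path; the penalty minimizing CV deviance is chosen (a
   one-standard-error rule is available by configuration) and the non-zero
   PCs at that penalty are tallied. Penalties not reached by every fold's
   path are excluded from the comparison — without this, incompletely
   evaluated penalties look spuriously good. The final set keeps PCs
   counted at least `min_count` times (default 5 per 100 iterations,
   scaled proportionally for reduced protocols) under **every** α.
5. **Linear collapse.** β = (MRDT/ln 2)·V_retained·β_PC per sex,
   β_CA = 1 + (MRDT/ln 2)(β_CA^cox − b), with C₀ absorbing all centering
   terms. The collapse is an algebraic identity; construction can assert
   max |linear BA − PC-path BA| < 1e−8 years on a verification cohort.

## Synthetic data

The generator emulates the structure of a cross-sectional survey with
linked mortality: ages uniform over 40–84 (a flat survey design, not a
population pyramid), two sexes drawn independently, features built as
loadings·latents + Gaussian noise rescaled to plausible clinical ranges,
and death times sampled exactly by inverting the Gompertz cumulative hazard
against a unit-exponential deviate — no discretization or rejection.
Censoring is administrative at a fixed horizon (default 20 years,
matching typical linked-mortality follow-up); random dropout is off by
default. Defaults: MRDT 8 years (b = ln 2/8 ≈ 0.0866/yr, a typical human
all-cause figure), intercept −9.8 calibrated to give a realistic
mid-life hazard (~1%/yr at age 60) and a 20-year event fraction around
one half in a 40–84 cohort; one to three latent factors with log-hazard
effects defaulting to (0.5, 0.3, 0, …). The default loading matrix depends
only on the problem shape, never on the subject seed, so cohorts and trials
from one configuration share a population structure.

The trial generator mirrors a two-arm caloric-restriction design: default
contrast 55 vs 97 subjects at true aging rates 1.5 vs 0.1 biological years
per calendar year over baseline/1 y/2 y visits. A rate of 1 is ordinary
calendar aging; since CA advances a year per year, latent factors drift by
the excess b·(rate − 1)·t along the mortality-effect direction, plus
per-subject Normal heterogeneity in the rate and fresh measurement noise at
each visit.

What the generator does **not** emulate: real marginal distributions of
specific analytes, missingness mechanisms that correlate with age or
health, competing causes of death, cohort batch effects, or measurement
drift between survey waves. Passing tests therefore demonstrate that the
estimators recover the generative model they assume — not that any
particular real cohort satisfies those assumptions.

## Evaluation conventions

* Quartile stratification labels the bottom/top quartiles of a score (or of
  score − CA in `delta` mode — both conventions appear in practice, so the
  mode is an explicit parameter) within each CA bin; cut points are
  computed per bin (optionally per sex), never globally. Default bins are
  decades 45–54 … 75–84.
* Horizon-mortality ROC excludes subjects censored before the horizon; with
  near-complete follow-up this is the least-biased simple rule
  (inverse-censoring weighting is out of scope). Paired AUCs are compared
  with DeLong's test (implemented here; no pre-installed package provides
  it).
* Measurement noise is multiplicative — each parameter scaled by
  (1 + ε), ε ~ N(0, 0.10) — matching the coefficient-of-variation framing
  of clinical assay variability. Clocks whose unperturbed score touches
  zero fall back to absolute errors in years.
* Cross-clock binning bins subjects by one score and quartile-stratifies
  each bin by the *residual* of the other score against the binning score,
  so identical scores yield no residual stratification by construction.
* The trial contrast fits ΔBA ~ time × arm on change-from-baseline values;
  per-arm rates and CIs come from linear contrasts, the arm difference from
  the two-way-ANOVA interaction term.

## Numerical choices and degenerate inputs

* Iterative-PCA imputation: mean initialization, rank-k reconstruction on
  standardized data, observed cells never modified; cap 10,000 iterations,
  tolerance 1e−6 on the largest absolute change, warning (not error) on
  non-convergence.
* Partial correlations come from the inverse covariance,
  ρᵢⱼ = −Ωᵢⱼ/√(Ωᵢᵢ Ωⱼⱼ); a singular covariance is a hard error rather than
  a pseudo-inverse fallback, to avoid silently unstable networks. Edges
  with |ρ| below the hard threshold (default 0.1) are removed; signs are
  retained.
* k-means uses k-means++ with 50 restarts by default; k is user-chosen
  (the package reports WCSS, it does not auto-select k). Ties in top-loading
  rankings break lexicographically by feature name.
* Missingness filtering is features-then-subjects (the order changes the
  outcome, so it is fixed); features above the threshold can be force-kept,
  mirroring the practice of retaining a biologically important marker
  despite elevated missingness.
* Follow-up is years internally; month-denominated inputs are converted at
  read time. Cox fitters require strictly positive durations, so simulated
  zero-time deaths are clipped to 1e−6 years.
* Warnings, not errors: |Δage| > 60 years, fewer than 30 events per sex,
  clusters or bins below the minimum advisable size.

## Known limitations

* Near-zero-variance PCs amplify measurement noise (their Cox coefficients
  scale inversely with score spread); the noise-robustness advantage of
  many-feature clocks is demonstrated at a fixed retained dimension.
  Practitioners should treat very small singular values with suspicion.
* The null-model MRDT on a cohort with unobserved frailty is mildly
  attenuated relative to the generative slope (a generic property of
  marginal proportional-hazards fits), so recovered MRDTs sit slightly
  above truth at realistic effect sizes; the parameter-recovery tolerances
  account for this.
* Stability selection is sex-pooled by default; with strongly sex-specific
  component effects, run it per sex and intersect.
* No survey weights, no competing-risk decomposition, no time-varying
  covariates, and the Cox-plus-MRDT conversion is the only fitting engine
  (no parametric Gompertz regression).
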