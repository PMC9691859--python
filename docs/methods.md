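# Methods

This note documents the statistical procedures implemented in `codshift`,
their assumptions, defaults, and limits.

## Cohort and conditioning

All analyses condition on death: the unit is a deceased patient, and a
cause's "risk" is its share among all deaths.  There are no person-time
denominators and no censored patients anywhere in the package.  The analysis
set applies two restrictions before era comparisons:

* deaths with an unknown/unrecorded cause are removed (they are counted and
  reported separately, ~2% under the default generator);
* deaths later than the follow-up cutoff are dropped.  `survival_months` is
  a completed-month count, so "died within three years" is implemented as
  `survival_months <= 35` under the default cutoff of 36.  The boundary
  convention is configurable because registry month coding is ambiguous on
  this point.

Era membership is determined solely by diagnosis year: pre era 2000–2011,
comparison era 2015–2017, with 2012–2014 (ambiguous adoption window) and
2018 (incomplete 3-year follow-up) excluded from grouped analyses.  The
clustering stage intentionally uses *all* years including the excluded ones,
so the ambiguous years can be seen falling on either side of the partition.

## Synthetic cohort generator

The generator emulates a registry extraction of deceased metastatic lung
cancer patients.  Per record:

* diagnosis year ~ uniform over 2000–2018;
* survival months ~ geometric with a constant per-month hazard
  (pre 0.066, post 0.055).  The pre value solves
  (1 − h)^36 ≈ 0.086, i.e. roughly 8.6% of patients alive at three years;
  the post value encodes a modest survival improvement.  A constant hazard
  is deliberately the simplest model that concentrates deaths in the first
  three years; only the month-grid structure matters downstream;
* cause ~ multinomial from the era's mix, modified multiplicatively by the
  record's covariate levels and renormalized.  The default mixes put lung
  cancer at 0.86, other cancers at 0.07, non-cancer causes at 0.05 and
  unknown at 0.02 pre-shift; post-shift every non-cancer cause is scaled by
  1.6 (share 0.05 → 0.08) with a compensating lung-cancer decrease.  This
  planted shift *is* the study condition the downstream recovery checks
  target; it is not a tuning knob;
* covariates (sex, binary age group, race, radiotherapy, chemotherapy) are
  independent Bernoulli/categorical draws.  The prevalences (female 0.45,
  ≥60 0.65, black 0.11, AI/AN/AP 0.09, radiotherapy 0.40, chemotherapy
  0.45) are arbitrary round numbers in the plausible range for this
  population; no registry-derived covariate distribution was available to
  calibrate against, and nothing downstream depends on their exact values.
  Default covariate effects (e.g. age ≥60 raising chronic-disease causes)
  create realistic confounding structure; `covariate_rr_post` lets effects
  differ by era.

An optional transition window interpolates mixes and hazards linearly across
a span of years to emulate gradual adoption.

What the generator does **not** emulate: stage migration, treatment
assignment, cause-specific survival differences (cause and survival month
are independent given the era), seasonal or registry-coding artifacts, and
living patients.  Passing recovery tests therefore show the estimators are
correct under the stated model, not that real registry data satisfy it.

## Empirical-Bayes smoothing

For dot (i, j) and cause c the death probability gets the conjugate prior
Beta(N_j Θ_i^c, N_j − N_j Θ_i^c) with posterior mean
θ̂ = (N_j Θ_i^c + m_ij^c) / (N_j + n_ij).  Choices made where the procedure
was open:

* **Θ is per cause as well as per year** (Θ_i^c = Σ_j m_ij^c / Σ_j n_ij).
  Only this reading makes Σ_c Θ_i^c = 1 and hence every smoothed row sum to
  1 exactly.
* **N_j averages n_ij over years at fixed month** (cells absent from the
  grid count as zero), so the prior weight equals the size of a typical dot
  of that month.
* **Priors are computed on the unfiltered grid**; the < 20-death dot filter
  is applied afterwards, as clustering pre-processing only.  Computing the
  prior from all data is the more stable ordering.
* Only the posterior mean is used as a feature.  `epsilon` (default 1e-6)
  floors degenerate Beta parameters in optional density evaluations; the
  mean formula needs no flooring, and the N_j = n = 0 corner returns the
  prior mean.

Exact invariants (tested): rows sum to 1; each θ̂ lies weakly between prior
and raw proportion; |θ̂ − m/n| is nonincreasing in n and nondecreasing in
N_j; dots with counts proportional to Θ are fixed points.

## Pattern clustering

K-means (squared Euclidean, Lloyd, best of 10 restarts, seeded) runs on the
smoothed feature matrix with per-cause z-scoring; without standardization
the dominant cause (~0.85) would swamp the rare causes that carry the era
signal.  k = 2 by default, matching the two-era design.  Clustering on the
UMAP embedding instead is available behind a flag but is not the default:
the embedding is nonlinear and seed-dependent, so clustering the features
is the reproducible choice, with UMAP reserved for visualization.  Year
patterns are majority votes over each year's dots; exact ties are reported
as ambiguous (cluster −1) rather than broken arbitrarily.

## Relative risks

The era effect on each cause's share among deaths is estimated two ways:

* **crude**: closed-form ratio of proportions with log-scale Wald SE
  sqrt(1/c1 − 1/t1 + 1/c0 − 1/t0);
* **adjusted**: Poisson log-linear model on the (era × sex × age group ×
  race) stratified count table with log(total deaths) offset and
  main-effect indicators, fitted by IRLS (statsmodels GLM, tolerance
  1e-10).  With no adjustment axes this collapses exactly to the crude
  estimate, which serves as a closed-form oracle in the tests; an
  independent BFGS maximization of the likelihood agrees to 1e-6.

Main effects only — with binary/ternary adjusters and deaths as denominator
there is no basis for interaction terms.  Zero cells and separation (a
cause absent from one era) get a 0.5 continuity correction and a flag,
never silently.  Benjamini–Hochberg adjusted p-values are reported alongside
the raw ones for convenience but gate nothing.  Excess deaths per 100,000
deaths are the proportion difference × 1e5, sign-consistent with RR by
construction.

## Hazard curves and era contrast

Monthly risk = deaths in month / patients alive at month start, within the
deceased-only, cutoff-truncated group.  Under this conditioning the
life-table identity holds exactly (tested): the cumulative product of
(1 − all-cause risk) equals the empirical survivor fraction, reaching 0 at
the last observed month.  Note the truncation inflates late-month risks
(everyone remaining must die by the window's end); both eras are distorted
identically, so *ratios* of matching curves remain interpretable.

Lowess is implemented classically: for each point a tricube-weighted linear
fit over the ⌈frac·n⌉ nearest neighbours, then bisquare robustifying
passes.  Defaults frac = 0.3, 1 robust pass — a documented default where
none is standard; the recovery checks are span-insensitive because the
underlying curves are locally near-linear.  The fit is exact on linear data
and deterministic.  AUC is the trapezoidal integral over the month grid;
the era contrast is 100 × (AUC_pre − AUC_post)/AUC_pre on the smoothed
curves.

The Wilcoxon matched-pairs signed-rank test pairs the two eras' *raw*
monthly risks (using smoothed values would double-use the smoother; a flag
allows it).  Zero differences are dropped, ties get average ranks, the
two-sided p is exact by full sign enumeration for ≤ 12 informative pairs
and a tie-corrected normal approximation with continuity correction above.

### Recovery check design

The planted-parameter check for the AUC contrast scales the post-era
all-cause hazard by 0.7 with identical cause mixes.  Because cause and
month are independent in the generator, every cause group's monthly risk is
hazard × share, so the planted ratio is global and the expected reduction
is 30%.  It is read out on the dominant (lung) cause group and on
*untruncated* era cohorts: truncation sends the at-risk tail toward zero
and risk toward 1 at the window end, which blows up the AUC variance of
rare cause groups far beyond what the dominant group's readout of the same
global parameter exhibits.  Problem sizes used throughout the checks —
200,000 records × 20 seeds for pattern recovery, 500 replicates at 50,000
for RR coverage, 100,000 per era for the hazard contrast, 1,000 random
cubes for smoothing invariants — were chosen so each planted parameter is
measured with comfortable precision at desk scale.

## Numerical and degenerate-input conventions

* All randomness flows through `numpy.random.default_rng` seeds; pipeline
  stages derive their seeds from the config seed via fixed offsets.
* Dots with nobody at risk are dropped from hazard grids; empty groups,
  zero-death years, and all-unknown cohorts raise or warn explicitly.
* K-means with identical rows, both-zero RR cells, and all-zero Wilcoxon
  differences return flagged degenerate results rather than raising.

## Known limitations

* Era is a proxy for treatment; the package deliberately does not model
  actual therapy receipt.
* The Poisson RR treats strata counts as independent Poisson draws; for a
  cause occupying a large share of deaths the binomial nature of the counts
  makes the Wald CI slightly conservative.
* The generator's independence assumptions (cause ⟂ survival month given
  era) mean cause-specific hazard *shapes* cannot be planted, only levels.
* UMAP coordinates are only reproducible for a fixed seed, library version
  and thread count; nothing quantitative depends on them.
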