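# codshift

Tools for asking how the *landscape of causes of death* among deceased cancer
patients shifted between two diagnosis-year eras — for example, before and
after immune checkpoint inhibitors entered routine care for metastatic
non-small-cell lung cancer.  The intended users are cancer epidemiologists
working with registry-style extracts of deceased patients (one row per death:
diagnosis year, survival months, cause-of-death recode, demographics).

Because real registry microdata are access-restricted, the package ships a
first-class synthetic cohort generator that reproduces the statistical
structure such analyses assume (geometric survival-month distribution,
multinomial cause mix with a planted era shift, covariate effects), so every
stage is testable end to end.

## The statistics

**Empirical-Bayes smoothing.**  Each (diagnosis year *i*, survival month *j*)
cell of deceased patients is a *sample dot* with total deaths *n<sub>ij</sub>*
and per-cause counts *m<sub>ij</sub>*.  For each cause the death probability
θ<sub>ij</sub> gets a conjugate Beta prior centred on the year-level cause
share Θ<sub>i</sub> with prior weight N<sub>j</sub> (the mean dot size of
month *j* across years):

  θ<sub>ij</sub> ~ Beta(N<sub>j</sub>Θ<sub>i</sub>, N<sub>j</sub> − N<sub>j</sub>Θ<sub>i</sub>),  θ̂<sub>ij</sub> = E(θ<sub>ij</sub> | data) = (N<sub>j</sub>Θ<sub>i</sub> + m<sub>ij</sub>) / (N<sub>j</sub> + n<sub>ij</sub>)

The posterior means shrink noisy late-month proportions toward the year's
overall mix, damping survival-month noise while preserving the
diagnosis-year structure of interest.  Rows sum to 1 exactly.

**Pattern discovery.**  K-means (k = 2, best of 10 restarts) on the z-scored
smoothed features partitions the dots into death-cause patterns (dots with
< 20 deaths are excluded first); each year is assigned its majority pattern.
A seeded UMAP embedding is provided for visualization only.

**Era contrasts.**  For each cause and cause group the package reports era
proportions, the crude risk ratio, an adjusted relative risk from a Poisson
log-linear model on the (era × sex × age × race) count table with
log(total deaths) offset, subgroup RRs, and excess deaths per 100,000
deaths.  Monthly death risks (deaths / at-risk at month start) are smoothed
with classical Lowess; era change is summarized as the percent reduction in
the area under the smoothed curve, tested with the Wilcoxon matched-pairs
signed-rank test (exact for ≤ 12 informative pairs).

## Worked example

```python
import codshift as cs

rec = cs.generate_cohort(cs.default_config(n_records=100_000, seed=7))
retained, _ = cs.apply_exclusions(rec)

pat = cs.DeathPatternModel(retained).fit(k=2, seed=7)
print(pat.summary())

model = cs.CauseShiftModel(rec)
print(model.fit().summary())
print(cs.HazardContrast(model.pre, model.immuno).fit().summary())
```

The pattern summary partitions the years cleanly at the planted 2015 shift
(pattern 1 = pre years, pattern 0 = post years):

```
Death-cause pattern clustering
  dots clustered : 683
  k              : 2
  ...
    2014: pattern 1 (0.71)
    2015: pattern 0 (0.94)
    2016: pattern 0 (0.89)
```

The cause-mix table recovers the planted non-cancer shift (share 5% → 8%,
i.e. RR ≈ 1.6) and the compensating lung-cancer decrease:

```
  cause               pre %   imm %      RR            95% CI         p  excess/100k
  LUNG_CANCER          86.3    82.6   0.956    [0.937, 0.976]   2.1e-05      -3774.6
  NON_CANCER            6.6    10.5   1.581    [1.487, 1.681]   8.1e-49       3862.1
```

and the hazard contrast shows the planted survival improvement as a positive
lung-cancer risk reduction and the non-cancer share increase as a negative
one:

```
  cause group        AUC pre   AUC imm  reduction %  Wilcoxon p
  LUNG_CANCER         3.6971    3.4209          7.5    4.88e-05
  NON_CANCER          0.3602    0.5002        -38.8    1.61e-05
```

A CLI mirrors the library (`codshift simulate|cluster|rr|hazard|all`); see
`codshift --help`.

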