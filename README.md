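# airway-turnover

Longitudinal analysis of airway-microbiome community turnover for
cohorts of mechanically ventilated preterm infants, where serial
tracheal aspirates (targeted at enrollment, 7, 14 and 21 days of age)
are profiled as taxon count tables and related to the severity of
bronchopulmonary dysplasia (BPD). The package is aimed at
biostatisticians and microbiome researchers who need the repeated-
measures machinery for such designs — not per-sample summaries alone,
but statistics of *change within a subject*.

## What it computes

**Effective number of communities.** For subject *i* with samples *j*
and taxa *k* (counts *c_ijk*, depths *c_ij+*, subject total *c_i++*),
the multi-sample Shannon beta diversity

  Hβ_i = Σ_j (c_ij+/c_i++) Σ_k (c_ijk/c_ij+) ln[(c_ijk/c_ij+) / (c_i+k/c_i++)]

is the abundance-weighted divergence of each sample from the subject's
pooled composition (equivalently, a mutual information). Its
exponential, a Hill number, is the effective number of communities the
subject's samples represent — 1 for identical samples up to *N* for *N*
disjoint equal-depth samples — and `(e^{Hβ}−1)/(j_i−1)` normalises it to
[0, 1] across subjects with different sample counts.

**Pairwise turnover.** Morisita-Horn similarity
`MH = 2Σp_k q_k / (Σp_k² + Σq_k²)` for every within-subject sample
pair (depth-invariant; lower = more turnover), compared across outcome
groups by a log-normal GEE with exchangeable working correlation and
sandwich standard errors — the same GEE machinery fits the time trend of
total bacterial load (log10 copies/reaction per week).

**Taxon trajectories.** A beta-binomial join-point generalized linear
mixed model for the relative abundance of a target taxon over postnatal
age: group-specific logit-linear segments with a slope change at a knot
(day 10 by default, or selected by the cubic-derivative rule), a subject
random intercept integrated out by adaptive Gauss–Hermite quadrature,
and group-specific dispersions. Group contrasts of population-average
relative abundance at any day come with delta-method Wald inference.

Alpha diversity (Shannon, Pielou evenness, rarefied Good's coverage)
and the cross-sectional day-7 comparison are included, plus a synthetic
cohort generator that emulates the sampling design (group sizes 25/30/39,
2–4 samples per subject with median 2, depths 6 451–196 691, communities
dominated by *Staphylococcus* and *Ureaplasma*) so the whole pipeline is
testable end to end. See `docs/methods.md` for model details.

## Worked example

Simulate a cohort and run both analyses (any fixed seed is fully
reproducible):

```sh
airway-turnover all --seed 1 --outdir results/demo
```

`results/demo/report.txt` from this exact command:

```
longitudinal analysis (config_hash=ea066b0ff3db seed=1)
subjects with >= 2 samples: 94
  median normalized Hill [mild]: 0.044
  median normalized Hill [moderate]: 0.123
  median normalized Hill [severe]: 0.191
  MH geometric mean [mild]: 0.802
  MH geometric mean [moderate]: 0.585
  MH geometric mean [severe]: 0.437
  MH contrast mild vs moderate: log-diff=0.316 (p=0.000)
  MH contrast mild vs severe: log-diff=0.607 (p=0.000)
  MH contrast moderate vs severe: log-diff=0.291 (p=0.011)
  load slope: 1.071 log10 copies/reaction per week (p=1.24e-220)
  join-point fit Staphylococcus: knot=10.0d, sigma_b=0.759, loglik=-2246.8
    RA contrast at day 14 mild vs moderate: +0.1266 (p=0.033)
    RA contrast at day 14 mild vs severe: +0.2827 (p=0.000)
    ...
```

Reading this: the 94 retained subjects split 25/30/39 across
mild/moderate/severe BPD. Turnover is ordered with severity in both
measures — the median normalized Hill number rises (more effective
communities per subject) while mean Morisita-Horn similarity falls from
mild to severe, and the GEE contrasts confirm the group differences with
repeated-measures-robust p-values. Total bacterial load grows by about
1.07 log10 copies/reaction per week (the generating value is 1.05). The
join-point fit shows *Staphylococcus* relative abundance at day 14
higher in mild than severe by 0.28 (fraction scale, p < 0.001),
mirroring the generator's group-graded trajectories. The cross-sectional
day-7 comparison (`report_cross_sectional.txt`) finds no group
differences in Shannon diversity, evenness or load — differences here
live in the longitudinal structure, not in any single snapshot.

The same analyses run on real data from a tab-delimited count table
(samples × taxa) and a metadata CSV with columns
`sample_id,subject_id,collection_day,group[,bacterial_load_log10]`:

```sh
airway-turnover longitudinal --config my_run.yaml
```

Library use mirrors the CLI: `read_count_table`, `build_subject_series`,
`pairwise_turnover`, `fit_betabin_joinpoint`, `fit_gee_lognormal`, etc.
(see `airway_turnover/__init__.py` for the public surface).

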