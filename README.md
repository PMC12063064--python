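# wavelpr

Clonal-trajectory analysis of liver and lung metastases from routine CT
diameter measurements: dispatch-wave clustering, the **linear/parallel ratio
(LPR)**, cohort summary tables, and dual-origin Kaplan–Meier survival
analysis — plus a seeded generative simulator of metastatic cohorts.

## The scientific problem

Metastatic spread is commonly idealised as one of two trajectories.  Under
**linear** dissemination, fully malignant clones leave the primary tumor in
discrete waves; the metastases of one wave land in the same organ at the
same time, grow at a similar rate, and therefore show near-identical
diameters on any single scan.  Under **parallel** dissemination, immature
disseminated tumor cells spread early and mature independently in the
target organ, so their diameters are dispersed.  Which route dominates has
direct clinical consequences: if spread is linear and early, metastases are
already present (but undetectable) at the primary diagnosis, and local
treatment of "localized" disease cannot prevent them.

This package operationalises the diameter-based test of that question for
cohorts of patients with lung and/or liver metastases (the motivating
setting is pancreatic ductal adenocarcinoma):

1. **Waves.**  Per patient and organ, the measured largest diameters are
   sorted and clustered with an organ-specific tolerance — 1 mm for lung,
   3 mm for liver (liver CT measurement is less precise).  A *wave* is a
   cluster of ≥ 2 diameters; a diameter that joins no cluster is *isolated*.
2. **LPR.**  With Σc the number of clustered and Σi the number of isolated
   metastases,

   ```
   LPR = (Σc − Σi) / (Σc + Σi)   ∈ [−1, +1]
   ```

   +1 means every metastasis clusters (pure linear spread), −1 that none do
   (pure parallel spread).
3. **Cohort tables.**  Medians with interquartile ranges of per-patient
   parameters (metastasis count, LPR, mean/SD/largest diameter, wave and
   singleton counts), cohort composition, and synchronous-vs-metachronous
   comparisons by two-sided Student's t-test.
4. **Dual-origin survival.**  Kaplan–Meier curves computed twice — from the
   primary diagnosis and from the metastasis diagnosis — and compared with
   the Gehan–Breslow generalized Wilcoxon test.  If synchronous and
   metachronous patients share the same post-metastasis hazard, the curves
   separate from the first origin by a pure *lead time* and coincide from
   the second.
5. **Simulator.**  A seeded generative model of all of the above (wave
   structure vs. dispersed diameters, organ mix, lead times, shared
   exponential post-metastasis hazard, administrative censoring), with a
   ground-truth sidecar, so every stage is testable without clinical data.

## Worked example

```python
from wavelpr import (SimScenario, simulate_cohort, summarize_cohort,
                     cohort_table, dual_origin_analysis)

cohort = simulate_cohort(SimScenario(seed=7))      # 133-patient cohort
summaries = summarize_cohort(cohort.sets)          # waves + LPR per patient-organ
print(cohort_table(summaries, "lung").to_string(index=False))
```

```
                       parameter    median   iqr_low  iqr_high  n
                          Number 10.000000  5.750000 18.000000 56
           Linear/parallel ratio  1.000000  0.903571  1.000000 56
Average metastasis diameter (mm) 10.136111  8.600549 11.408125 56
         Standard deviation (mm)  2.554584  0.423634  3.168679 56
         Largest metastasis (mm) 13.700000 11.550000 14.700000 56
              Number of clusters  2.000000  1.000000  3.000000 56
     Number of single metastases  0.000000  0.000000  1.000000 56
```

The median lung LPR of +1 is the linear-dissemination signature: in a
typical patient every metastasis belongs to a diameter wave.  The survival
side of the same question:

```python
dual = dual_origin_analysis(cohort.patients)
for (origin, group), curve in sorted(dual.curves.items()):
    print(f"{origin:13s} {group:12s} median {curve.median_months} months")
for origin, comp in dual.comparisons.items():
    print(f"{origin}: {comp.test_name} p = {comp.p_value:.4f}")
```

```
metastasis_dx metachronous median 7.7 months
metastasis_dx synchronous  median 6.3 months
primary_dx    metachronous median 21.0 months
primary_dx    synchronous  median 6.3 months
primary_dx: gehan-wilcoxon p = 0.0000
metastasis_dx: gehan-wilcoxon p = 0.1597
```

Metachronous patients appear to live far longer — but only when the clock
starts at the primary diagnosis.  From the metastasis diagnosis the two
groups are statistically indistinguishable: the survival advantage is lead
time, not different disease biology.

## Command line

The same pipeline as subcommands (each writes its resolved config, a run
log and plain CSV/JSON outputs):

```bash
wavelpr simulate --out sim/ --seed 7                 # cohort + truth + report
wavelpr lpr      --metastases sim/metastases.csv --patients sim/patients.csv --out lpr/
wavelpr survival --patients sim/patients.csv --metastases sim/metastases.csv --out surv/
wavelpr report   --in lpr/                           # aligned plain-text tables
```

`wavelpr lpr` accepts `--linkage single|complete` (how "diameter difference
within tolerance" is chained), `--lung-tolerance/--liver-tolerance`, and
`--quantile-rule linear|nearest_rank`.

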