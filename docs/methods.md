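# Methods

## Wave clustering and the linear/parallel ratio

The unit of analysis is one patient-organ multiset of largest metastasis
diameters (mm, 0.1 mm precision).  Clustering is one-dimensional: diameters
are sorted ascending and split by a gap rule at an organ-specific tolerance
(lung 1.0 mm, liver 3.0 mm; the liver value is coarser because manual liver
CT measurement is less precise).  Gaps exactly equal to the tolerance are
clustered (the rule is "≤"), implemented with a 1e-9 mm slack so the
boundary survives float arithmetic.

"Diameter difference within tolerance" does not by itself say *between
which pairs*, so two linkage conventions are provided:

* **single** (default): a wave breaks wherever an adjacent sorted gap
  exceeds the tolerance.  Deterministic, order-free and parameter-free, and
  provably Σc-maximal: any valid block of a contiguous partition lies
  inside one maximal run, and splitting a run never increases the clustered
  count.  The test suite verifies this equivalence against brute-force
  enumeration of all contiguous partitions for n ≤ 8.
* **complete**: a wave's total spread (max − min) may not exceed the
  tolerance; waves are formed greedily left-to-right from the smallest
  diameter.  Greedy complete linkage is canonical and reproducible but not
  Σc-maximal (for diameters 0, 0.9, 1.0, 1.9 at tolerance 1 it yields
  {0, 0.9, 1.0} + isolated {1.9}, clustering 3, whereas {0, 0.9} + {1.0,
  1.9} clusters all 4).  It is retained as a sensitivity option; results
  tables record which rule was used.

A cluster needs ≥ 2 members; singletons are isolated.  The LPR is
(Σc − Σi)/(Σc + Σi).  For a single metastasis the formula gives −1; rather
than suppressing the value, sets with fewer than `min_n` (default 3)
diameters carry a low-confidence flag, and flagged patients are *included*
in cohort medians (a configuration switch excludes them).  The accuracy of
the LPR genuinely degrades at small metastasis counts, which is why the
flag exists.

## Cohort statistics

Cohort tables report the median and IQR of each per-patient parameter.
Quantiles use linear interpolation between order statistics by default; a
nearest-rank rule is available because the two differ at small n and the
convention used by any given report is rarely stated.  Group comparisons
(metachronous vs. synchronous) apply a two-sided Student's t-test to the
raw per-patient values — pooled-variance by default, Welch as an option —
with α = 0.05 and no multiple-testing correction, matching the reporting
style of the clinical literature this mirrors.  Medians are reported next
to t-based p-values deliberately: that combination is what such studies
print, and the caveat that the test is on means while the table shows
medians applies to them as it does here.

## Survival

Overall survival is estimated by the product-limit (Kaplan–Meier)
estimator (via `lifelines`), with deaths counted before censorings at tied
times.  The median is the smallest time with S(t) ≤ 0.5; its 95% CI comes
from intersecting the exponential-Greenwood (complementary log-log)
confidence band with 0.5.  A median that is never reached is an explicit
`None`, never infinity in arithmetic.  Horizon survival uses the
right-continuous step convention, so S(6) is the value *at* month 6.

Curves are compared with the Gehan–Breslow generalized Wilcoxon test
(event weights equal to the number at risk, chi-square on 1 df), the
standard "Wilcoxon test for survival curves"; it upweights early events,
which suits a disease where most deaths occur within a year.  A log-rank
option is provided for sensitivity.  Groups with zero events are flagged;
two event-free samples degenerate to statistic 0, p = 1.

Every analysis runs from two time origins — primary diagnosis and
metastasis diagnosis — because the difference between them is the
diagnostic for lead time: with a shared post-metastasis hazard, the
primary-origin group medians differ by approximately the metachronous
detection interval while the metastasis-origin comparison is null.  The
`dual_origin_analysis` report includes this difference-of-differences
explicitly.  Only overall survival is modelled; no competing-risks
machinery (in the motivating setting ~98% of deaths are disease-specific).

## The generative simulator

The simulator parameterizes final diameters directly (wave means plus
measurement noise) rather than modelling growth kinetics, since only the
diameter structure at a single scan enters the LPR.  Defaults describe the
reference cohort the analysis was built around:

| parameter | default | rationale |
|---|---|---|
| n_patients | 133 | reference cohort size |
| organ mix (liver-only/lung-only/both) | 0.601/0.203/0.196 | observed involvement pattern |
| P(metachronous) | 0.271 | observed timing mix |
| wave count K | 1–6, mode 2 (lung) / 3 (liver) | observed cluster-count medians |
| metastases per wave | geometric, mean 6 (lung) / 4 (liver) | reproduces count medians ≈ 10–12 with a long right tail |
| wave means | uniform with min separation 2·tol + 0.2 mm, lung 4–15 mm, liver 8–40 mm | organ-typical sizes; separation keeps true waves resolvable |
| measurement noise sd | 0.3 mm (lung) / 1.0 mm (liver) | below the clustering tolerances, mirroring the precision rationale for the tolerances themselves |
| parallel diameters | i.i.d. uniform, lung 4–30 mm, liver 5–60 mm | independent maturation over the organ-typical size range |
| lead time (metachronous) | lognormal, median 7.5 mo, log-sd 1.0 | fits the observed median and IQR (≈ 4.3–15.8 mo) |
| post-metastasis survival | exponential, median 7 mo, **shared by both timing groups** | encodes the lead-time-only null structure |
| censoring | independent exponential, ≈ 10% censored | administrative end-of-follow-up |
| detection floor | 1 mm, rounded to 0.1 mm | CT detectability and reporting precision |

Diameter truth (wave label and dispatched size per metastasis) is written
alongside the cohort, enabling parameter-recovery tests: at zero noise the
estimated wave count equals the number of true waves with ≥ 2 members for
K ≤ 4, and single-wave low-noise lung scenarios give median cohort
LPR = +1 exactly.

### What the simulator does and does not emulate

It emulates the features the pipeline's inferences rest on: wave-structured
vs. dispersed diameters, organ-specific precision, the timing mix, a pure
lead-time survival difference, and administrative censoring.  It does
**not** couple metastasis counts to timing (so surveillance effects — e.g.
metachronous patients presenting with fewer, smaller lung metastases — are
absent), does not model growth kinetics, inter-organ correlation within a
patient, or detection-probability curves.  Passing recovery tests therefore
demonstrates that the pipeline measures what the generative model encodes,
not that real cohorts satisfy that model.

### A known limitation of the LPR on dispersed sets

For parallel (i.i.d.) diameters the LPR does *not* approach −1 at
realistic metastasis counts.  With n diameters uniform on a range of width
W, an adjacent sorted gap falls below the tolerance t with probability
≈ 1 − (1 − t/W)^(n−1); at n ≈ 10–12 in a 26 mm lung range roughly half the
metastases chain into spurious clusters and the median LPR saturates near
0 (Monte-Carlo: median 0.0, IQR −0.2 to +0.4).  Driving the median below
−0.5 would require size ranges several times wider than organs exhibit.
The statistic therefore separates *linear* (≈ +1) from *parallel* (≈ 0 to
+0.4) cleanly in the lung, more weakly in the liver where the 3 mm
tolerance clusters much of any dispersed set; a strongly negative LPR
should be expected only for patients with few, widely spaced metastases.

## Numerical and reporting choices

Problem sizes in the automated checks (cohorts of 133–200 patients,
100-replicate null experiments, 1000-replicate engine calibrations) were
chosen so each check is decisive at its tolerance while the whole suite
stays fast.  All randomness flows through a single `numpy` generator seeded
per scenario, so cohorts are reproducible byte-for-byte.  Validation never
silently drops data: rejected rows are reported with reasons and
`accepted + rejected = input` is an invariant.  Percentages are reported to
one decimal; diameters at 0.1 mm; times in months throughout.
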