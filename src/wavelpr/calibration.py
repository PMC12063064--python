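"""Monte-Carlo calibration of the statistical engines.

Null-hypothesis replicate simulations checking that the two-sample t-test
and the Gehan-Breslow-Wilcoxon curve test reject at close to the nominal
rate, and that the Kaplan-Meier estimate coincides with the empirical
survivor function when nothing is censored.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .cohort_stats import ALPHA
from .survival import SurvivalRecord, km_fit, survival_at, wilcoxon_compare


def ttest_type1_rate(
    n_reps: int = 1000,
    n_per_group: int = 50,
    alpha: float = ALPHA,
    seed: int = 0,
) -> float:
    """Rejection rate of the pooled t-test on two Normal(0,1) samples."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n_reps, n_per_group))
    b = rng.normal(size=(n_reps, n_per_group))
    p = stats.ttest_ind(a, b, axis=1, equal_var=True).pvalue
    return float(np.mean(p < alpha))


def gehan_type1_rate(
    n_reps: int = 1000,
    n_per_group: int = 60,
    alpha: float = ALPHA,
    seed: int = 0,
    censor_fraction: float = 0.1,
) -> float:
    """Rejection rate of the Gehan-Wilcoxon test on two equal exponential arms."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        recs = []
        for group in ("a", "b"):
            t = rng.exponential(10.0, size=n_per_group)
            censored = rng.random(n_per_group) < censor_fraction
            recs.append(
                [
                    SurvivalRecord(f"{group}{i}", float(ti), 0 if c else 1, "metastasis_dx", group)
                    for i, (ti, c) in enumerate(zip(t, censored))
                ]
            )
        res = wilcoxon_compare(recs[0], recs[1])
        if res.p_value < alpha:
            rejections += 1
    return rejections / n_reps


def km_empirical_max_error(n: int = 200, seed: int = 0) -> float:
    """Max |KM - empirical survivor fraction| on a censoring-free sample.

    With no censoring the product-limit estimate must equal the empirical
    fraction surviving past each event time; returns the largest absolute
    discrepancy over all event times.
    """
    rng = np.random.default_rng(seed)
    t = np.round(rng.exponential(12.0, size=n), 2)
    recs = [SurvivalRecord(f"p{i}", float(ti), 1, "primary_dx") for i, ti in enumerate(t)]
    curve = km_fit(recs)
    km = np.array(survival_at(curve, list(curve.times)))
    empirical = np.array([(t > ti).mean() for ti in curve.times])
    return float(np.max(np.abs(km - empirical)))
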