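"""Cohort-level summary tables and between-group comparisons.

Aggregates per-patient metastasis summaries into the standard reporting
tables of a metastatic-cohort study: median with interquartile range per
parameter, categorical composition counts with percentages, and
synchronous-versus-metachronous comparisons.  Continuous parameters are
compared with a two-tailed Student's t-test on the raw per-patient values
(pooled-variance by default, Welch optional); p < 0.05 is flagged
significant.  Quantiles use linear interpolation between order statistics
by default, with a nearest-rank alternative since small-sample IQRs differ
between rules.
"""

from __future__ import annotations

from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import MetastasisSet, Organ, PatientRecord, Timing
from .wave_lpr import PatientMetastasisSummary

QuantileRule = Literal["linear", "nearest_rank"]

ALPHA = 0.05

#: (attribute on PatientMetastasisSummary, table label) in reporting order
PARAMETERS: tuple[tuple[str, str], ...] = (
    ("n_total", "Number"),
    ("lpr", "Linear/parallel ratio"),
    ("mean_diameter_mm", "Average metastasis diameter (mm)"),
    ("sd_diameter_mm", "Standard deviation (mm)"),
    ("largest_diameter_mm", "Largest metastasis (mm)"),
    ("n_waves", "Number of clusters"),
    ("n_isolated", "Number of single metastases"),
)


def quantile(values: Sequence[float], q: float, rule: QuantileRule = "linear") -> float:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("quantile of empty sequence")
    method = "linear" if rule == "linear" else "inverted_cdf"
    return float(np.quantile(arr, q, method=method))


def _parameter_values(
    summaries: Iterable[PatientMetastasisSummary], attr: str
) -> list[float]:
    vals = [getattr(s, attr) for s in summaries]
    return [float(v) for v in vals if v is not None]


def cohort_table(
    summaries: Sequence[PatientMetastasisSummary],
    organ: Organ | str | None = None,
    quantile_rule: QuantileRule = "linear",
) -> pd.DataFrame:
    """Median (IQR) of every metastasis parameter, optionally per organ.

    One row per parameter with columns ``parameter, median, iqr_low,
    iqr_high, n``.  Patients with a single metastasis contribute no sample
    SD, so that row's ``n`` may be smaller.
    """
    if organ is not None:
        organ = Organ(organ)
        summaries = [s for s in summaries if s.organ is organ]
    if not summaries:
        name = organ.value if isinstance(organ, Organ) else organ
        raise ValueError(f"no summaries after organ filter '{name}'")
    rows = []
    for attr, label in PARAMETERS:
        vals = _parameter_values(summaries, attr)
        rows.append(
            {
                "parameter": label,
                "median": quantile(vals, 0.5, quantile_rule),
                "iqr_low": quantile(vals, 0.25, quantile_rule),
                "iqr_high": quantile(vals, 0.75, quantile_rule),
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows)


def two_sample_t(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided Student's t-test; returns (statistic, p)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    summaries: Sequence[PatientMetastasisSummary],
    patients: Sequence[PatientRecord],
    organ: Organ | str,
    quantile_rule: QuantileRule = "linear",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Metachronous-vs-synchronous comparison of metastasis parameters.

    One row per parameter: median and IQR per timing group plus the
    two-sided t-test p-value on raw per-patient values.  A group with fewer
    than two patients gets an undefined (NaN) p-value for that row.
    """
    organ = Organ(organ)
    timing_of = {p.patient_id: p.timing for p in patients}
    organ_summaries = [s for s in summaries if s.organ is organ]
    groups = {
        Timing.METACHRONOUS: [s for s in organ_summaries if timing_of.get(s.patient_id) is Timing.METACHRONOUS],
        Timing.SYNCHRONOUS: [s for s in organ_summaries if timing_of.get(s.patient_id) is Timing.SYNCHRONOUS],
    }
    if not groups[Timing.METACHRONOUS] or not groups[Timing.SYNCHRONOUS]:
        raise ValueError("both timing groups must be non-empty")
    rows = []
    for attr, label in PARAMETERS:
        row: dict[str, object] = {"parameter": label}
        per_group_values = {}
        for timing, grp in groups.items():
            vals = _parameter_values(grp, attr)
            per_group_values[timing] = vals
            prefix = timing.value
            row[f"{prefix}_median"] = quantile(vals, 0.5, quantile_rule) if vals else np.nan
            row[f"{prefix}_iqr_low"] = quantile(vals, 0.25, quantile_rule) if vals else np.nan
            row[f"{prefix}_iqr_high"] = quantile(vals, 0.75, quantile_rule) if vals else np.nan
            row[f"{prefix}_n"] = len(vals)
        a, b = per_group_values[Timing.METACHRONOUS], per_group_values[Timing.SYNCHRONOUS]
        if len(a) >= 2 and len(b) >= 2:
            _, p = two_sample_t(a, b, equal_var=equal_var)
        else:
            p = np.nan
        row["p_value"] = p
        row["significant"] = bool(p < ALPHA) if np.isfinite(p) else False
        rows.append(row)
    return pd.DataFrame(rows)


def organ_pattern(patient_id: str, sets: Iterable[MetastasisSet]) -> str:
    """Classify a patient's organ involvement: liver_only/lung_only/both/none."""
    organs = {ms.organ for ms in sets if ms.patient_id == patient_id}
    if organs == {Organ.LIVER}:
        return "liver_only"
    if organs == {Organ.LUNG}:
        return "lung_only"
    if organs == {Organ.LUNG, Organ.LIVER}:
        return "both"
    return "none"


def composition_table(
    patients: Sequence[PatientRecord],
    sets: Sequence[MetastasisSet],
) -> pd.DataFrame:
    """Categorical cohort composition: counts and percentages.

    Covers sex, primary-tumor location, metastasis timing and organ
    involvement pattern.  Within each category the counts sum to the number
    of patients; percentages are reported to one decimal.
    """
    n = len(patients)
    pattern_of = {p.patient_id: organ_pattern(p.patient_id, sets) for p in patients}
    categories: list[tuple[str, str]] = []
    for p in patients:
        categories.append(("sex", p.sex.value))
        categories.append(("primary_location", p.primary_location.value))
        categories.append(("timing", p.timing.value))
        categories.append(("organ_pattern", pattern_of[p.patient_id]))
    order = {
        "sex": ["female", "male"],
        "primary_location": ["head", "body", "tail"],
        "timing": ["synchronous", "metachronous"],
        "organ_pattern": ["liver_only", "lung_only", "both", "none"],
    }
    rows = []
    for cat, levels in order.items():
        counts = {lvl: 0 for lvl in levels}
        for c, lvl in categories:
            if c == cat:
                counts[lvl] += 1
        for lvl in levels:
            if cat == "organ_pattern" and lvl == "none" and counts[lvl] == 0:
                continue
            rows.append(
                {
                    "category": cat,
                    "level": lvl,
                    "count": counts[lvl],
                    "percent": round(100.0 * counts[lvl] / n, 1) if n else 0.0,
                }
            )
    return pd.DataFrame(rows)


def format_table(df: pd.DataFrame) -> str:
    """Aligned plain-text rendering of any of the tables above."""
    return df.to_string(index=False, float_format=lambda v: f"{v:.3g}")
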