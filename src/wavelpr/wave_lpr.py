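"""Dispatch-wave clustering of metastasis diameters and the linear/parallel ratio.

Under linear dissemination, a wave of metastases leaves the primary tumor
together, lands in the same organ, grows at a similar rate and therefore
presents near-identical diameters on a single scan.  Under parallel
dissemination, disseminated tumor cells mature independently and diameters
are dispersed.  A *wave* is operationalized as a cluster of diameters whose
differences stay within an organ-specific measurement tolerance
(1 mm for lung, 3 mm for liver, the coarser liver tolerance reflecting the
lower precision of liver measurement).

The linear/parallel ratio summarizes one patient-organ diameter multiset::

    LPR = (sum_c - sum_i) / (sum_c + sum_i)

where ``sum_c`` counts metastases belonging to a cluster of size >= 2 and
``sum_i`` counts isolated metastases that join no cluster.  LPR = +1 means
every metastasis clusters (pure linear spread); LPR = -1 means none do
(pure parallel spread).

Clustering is one-dimensional and deterministic: diameters are sorted
ascending and split by a gap rule.  Two linkage conventions are provided,
because "diameter difference <= tolerance" does not say between which pairs:

* ``single`` (default): break a wave wherever an adjacent sorted gap exceeds
  the tolerance; within a wave consecutive diameters chain together.
* ``complete``: greedy leftmost-first; a wave's total spread (max - min) may
  not exceed the tolerance, so a new wave starts at the first diameter
  exceeding the current wave's minimum plus the tolerance.

Boundary ties (gap exactly equal to the tolerance) are clustered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, stdev
from typing import Iterable, Literal

from .cohort_io import MetastasisSet, Organ

Linkage = Literal["single", "complete"]

#: organ-specific clustering tolerances (mm)
DEFAULT_TOLERANCES_MM: dict[Organ, float] = {Organ.LUNG: 1.0, Organ.LIVER: 3.0}

#: below this set size the LPR is computed but flagged as low-confidence
DEFAULT_MIN_N = 3


@dataclass(frozen=True)
class WavePartition:
    """Partition of a diameter multiset into waves and isolated metastases.

    ``clusters`` holds the waves (each with >= 2 members, sorted ascending);
    ``isolated`` holds the singletons.  The union is exactly the input
    multiset.
    """

    clusters: tuple[tuple[float, ...], ...]
    isolated: tuple[float, ...]
    tolerance_mm: float
    linkage: Linkage


@dataclass(frozen=True)
class LprResult:
    """Linear/parallel ratio and wave counts for one partition.

    ``low_n`` marks sets too small for the ratio to be reliable; the value
    is still computed (a single metastasis is formally isolated, LPR = -1).
    """

    sum_clustered: int
    sum_isolated: int
    lpr: float
    n_waves: int
    n_isolated: int
    n_total: int
    low_n: bool


@dataclass(frozen=True)
class PatientMetastasisSummary:
    """Per-patient-per-organ metastasis parameters.

    ``sd_diameter_mm`` is the sample standard deviation and is ``None``
    for a single metastasis.
    """

    patient_id: str
    organ: Organ
    n_total: int
    mean_diameter_mm: float
    sd_diameter_mm: float | None
    largest_diameter_mm: float
    n_waves: int
    n_isolated: int
    lpr: float
    low_n: bool
    tolerance_mm: float
    linkage: Linkage


def default_tolerance(organ: Organ | str) -> float:
    """Clustering tolerance in mm for an organ: lung 1.0, liver 3.0."""
    try:
        organ = Organ(organ)
    except ValueError:
        raise ValueError(f"unknown organ '{organ}'")
    return DEFAULT_TOLERANCES_MM[organ]


def cluster_waves(
    diameters: Iterable[float],
    tolerance_mm: float,
    linkage: Linkage = "single",
) -> WavePartition:
    """Partition a diameter multiset into waves under the gap rule.

    Deterministic and independent of input order (diameters are sorted
    ascending first).  Runs of length one become isolated metastases.
    """
    values = sorted(float(d) for d in diameters)
    if not values:
        raise ValueError("empty metastasis set")
    if any(v <= 0 or not math.isfinite(v) for v in values):
        raise ValueError("diameters must be positive and finite")
    if not (tolerance_mm > 0):
        raise ValueError("tolerance_mm must be positive")
    if linkage not in ("single", "complete"):
        raise ValueError(f"unknown linkage '{linkage}'")

    # tiny slack so tolerance-boundary gaps stay "<=" under float arithmetic
    eps = 1e-9
    runs: list[list[float]] = []
    start = 0
    for i in range(1, len(values)):
        if linkage == "single":
            split = values[i] - values[i - 1] > tolerance_mm + eps
        else:  # complete: spread of the running wave may not exceed tolerance
            split = values[i] - values[start] > tolerance_mm + eps
        if split:
            runs.append(values[start:i])
            start = i
    runs.append(values[start:])

    clusters = tuple(tuple(r) for r in runs if len(r) >= 2)
    isolated = tuple(r[0] for r in runs if len(r) == 1)
    return WavePartition(clusters=clusters, isolated=isolated, tolerance_mm=tolerance_mm, linkage=linkage)


def compute_lpr(partition: WavePartition, min_n: int = DEFAULT_MIN_N) -> LprResult:
    """Evaluate LPR = (sum_c - sum_i)/(sum_c + sum_i) on a partition."""
    sum_c = sum(len(c) for c in partition.clusters)
    sum_i = len(partition.isolated)
    n_total = sum_c + sum_i
    if n_total == 0:
        raise ValueError("empty partition")
    lpr = (sum_c - sum_i) / n_total
    return LprResult(
        sum_clustered=sum_c,
        sum_isolated=sum_i,
        lpr=lpr,
        n_waves=len(partition.clusters),
        n_isolated=sum_i,
        n_total=n_total,
        low_n=n_total < min_n,
    )


def summarize_patient(
    ms: MetastasisSet,
    tolerance_mm: float | None = None,
    linkage: Linkage = "single",
    min_n: int = DEFAULT_MIN_N,
) -> PatientMetastasisSummary:
    """Waves, LPR and descriptive statistics for one patient-organ set."""
    tol = default_tolerance(ms.organ) if tolerance_mm is None else tolerance_mm
    partition = cluster_waves(ms.diameters, tol, linkage)
    lpr = compute_lpr(partition, min_n=min_n)
    diams = list(ms.diameters)
    return PatientMetastasisSummary(
        patient_id=ms.patient_id,
        organ=ms.organ,
        n_total=lpr.n_total,
        mean_diameter_mm=mean(diams),
        sd_diameter_mm=stdev(diams) if len(diams) > 1 else None,
        largest_diameter_mm=max(diams),
        n_waves=lpr.n_waves,
        n_isolated=lpr.n_isolated,
        lpr=lpr.lpr,
        low_n=lpr.low_n,
        tolerance_mm=tol,
        linkage=linkage,
    )


def summarize_cohort(
    sets: Iterable[MetastasisSet],
    tolerances_mm: dict[Organ, float] | None = None,
    linkage: Linkage = "single",
    min_n: int = DEFAULT_MIN_N,
) -> list[PatientMetastasisSummary]:
    """Summarize every patient-organ set with organ-appropriate tolerances."""
    tols = dict(DEFAULT_TOLERANCES_MM)
    if tolerances_mm:
        tols.update(tolerances_mm)
    return [summarize_patient(ms, tols[ms.organ], linkage, min_n) for ms in sets]
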