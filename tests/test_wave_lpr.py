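"""Wave clustering and linear/parallel ratio: examples, invariants, oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wavelpr.cohort_io import MetastasisSet, Organ
from wavelpr.wave_lpr import (
    cluster_waves,
    compute_lpr,
    default_tolerance,
    summarize_patient,
)

# ---------------------------------------------------------------------------
# independent brute-force oracle: best achievable clustered count over all
# contiguous partitions of the sorted diameters under the linkage rule
# ---------------------------------------------------------------------------

EPS = 1e-9


def _contiguous_partitions(values: list[float]):
    n = len(values)
    for splits in itertools.product([False, True], repeat=n - 1):
        blocks, start = [], 0
        for i, cut in enumerate(splits, start=1):
            if cut:
                blocks.append(values[start:i])
                start = i
        blocks.append(values[start:])
        yield blocks


def brute_force_max_clustered(diameters, tol, linkage="single") -> int:
    values = sorted(diameters)
    best = 0
    for blocks in _contiguous_partitions(values):
        if linkage == "single":
            ok = all(
                b[i + 1] - b[i] <= tol + EPS for b in blocks for i in range(len(b) - 1)
            )
        else:
            ok = all(b[-1] - b[0] <= tol + EPS for b in blocks)
        if ok:
            best = max(best, sum(len(b) for b in blocks if len(b) >= 2))
    return best


diam_lists = st.lists(
    st.floats(min_value=0.1, max_value=60.0, allow_nan=False).map(lambda x: round(x, 1)),
    min_size=1,
    max_size=10,
)


class TestClusterWaves:
    @pytest.mark.parametrize(
        "diameters,tol,linkage,clusters,isolated",
        [
            ([5.0, 5.5, 6.0, 8.0], 1.0, "single", [(5.0, 5.5, 6.0)], (8.0,)),
            ([5.0, 5.8, 6.6], 1.0, "single", [(5.0, 5.8, 6.6)], ()),
            ([5.0, 5.8, 6.6], 1.0, "complete", [(5.0, 5.8)], (6.6,)),
            ([7.0], 1.0, "single", [], (7.0,)),
            ([7.0], 100.0, "complete", [], (7.0,)),
            # boundary tie: gap exactly equal to the tolerance is clustered
            ([5.0, 6.0], 1.0, "single", [(5.0, 6.0)], ()),
            ([5.0, 8.0], 3.0, "complete", [(5.0, 8.0)], ()),
        ],
    )
    def test_examples(self, diameters, tol, linkage, clusters, isolated):
        part = cluster_waves(diameters, tol, linkage)
        assert list(part.clusters) == [tuple(c) for c in clusters]
        assert part.isolated == tuple(isolated)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cluster_waves([], 1.0)

    def test_bad_tolerance_and_linkage_rejected(self):
        with pytest.raises(ValueError):
            cluster_waves([5.0], 0.0)
        with pytest.raises(ValueError):
            cluster_waves([5.0], 1.0, "average")  # type: ignore[arg-type]

    @given(diam_lists)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_permutation_invariance_and_conservation(self, diameters):
        base = cluster_waves(diameters, 1.0)
        shuffled = list(reversed(diameters))
        assert cluster_waves(shuffled, 1.0) == base
        members = sorted(
            [d for c in base.clusters for d in c] + list(base.isolated)
        )
        assert members == sorted(diameters)

    @given(diam_lists, st.floats(min_value=0.1, max_value=5.0), st.floats(min_value=0.0, max_value=5.0))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_tolerance_monotonicity_single_linkage(self, diameters, tol, extra):
        lo = compute_lpr(cluster_waves(diameters, tol))
        hi = compute_lpr(cluster_waves(diameters, tol + extra))
        assert hi.sum_clustered >= lo.sum_clustered
        assert hi.lpr >= lo.lpr

    @given(diam_lists.filter(lambda d: len(d) <= 8))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_single_linkage_matches_bruteforce_max_clustered(self, diameters):
        res = compute_lpr(cluster_waves(diameters, 1.0, "single"))
        assert res.sum_clustered == brute_force_max_clustered(diameters, 1.0, "single")

    @given(diam_lists)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_complete_linkage_width_invariant(self, diameters):
        part = cluster_waves(diameters, 1.0, "complete")
        for c in part.clusters:
            assert max(c) - min(c) <= 1.0 + EPS

    @given(diam_lists)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_degenerate_tolerance_limits(self, diameters):
        # vanishing tolerance clusters only exact ties
        tiny = cluster_waves(diameters, 1e-9)
        for c in tiny.clusters:
            assert len(set(c)) == 1
        # tolerance covering the whole spread puts everything in one wave
        if len(diameters) >= 2:
            span = max(diameters) - min(diameters)
            wide = compute_lpr(cluster_waves(diameters, span + 1.0))
            assert wide.lpr == 1.0


class TestLpr:
    def test_all_clustered_is_plus_one(self):
        res = compute_lpr(cluster_waves([10.0, 10.2, 10.4], 1.0))
        assert res.lpr == 1.0 and res.sum_isolated == 0

    def test_none_clustered_is_minus_one(self):
        res = compute_lpr(cluster_waves([5.0, 10.0, 20.0], 1.0))
        assert res.lpr == -1.0 and res.sum_clustered == 0

    def test_three_one_split_is_half(self):
        res = compute_lpr(cluster_waves([6.0, 6.5, 6.5, 12.0], 1.0))
        assert (res.sum_clustered, res.sum_isolated) == (3, 1)
        assert res.lpr == 0.5

    @given(diam_lists, st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds_and_conservation(self, diameters, tol):
        res = compute_lpr(cluster_waves(diameters, tol))
        assert -1.0 <= res.lpr <= 1.0
        assert res.sum_clustered + res.sum_isolated == res.n_total == len(diameters)
        assert (res.lpr == 1.0) == (res.sum_isolated == 0)
        assert (res.lpr == -1.0) == (res.sum_clustered == 0)

    def test_low_n_flag(self):
        assert compute_lpr(cluster_waves([5.0], 1.0)).low_n
        assert compute_lpr(cluster_waves([5.0, 5.5], 1.0)).low_n
        assert not compute_lpr(cluster_waves([5.0, 5.5, 6.0], 1.0)).low_n


class TestDefaultTolerance:
    def test_organ_values(self):
        assert default_tolerance(Organ.LUNG) == 1.0
        assert default_tolerance("liver") == 3.0

    def test_unknown_organ(self):
        with pytest.raises(ValueError, match="unknown organ"):
            default_tolerance("kidney")


class TestSummarizePatient:
    def test_lung_example(self):
        ms = MetastasisSet("P1", Organ.LUNG, (6.0, 6.5, 6.5, 12.0))
        s = summarize_patient(ms)
        assert s.n_total == 4
        assert s.largest_diameter_mm == 12.0
        assert s.n_waves == 1 and s.n_isolated == 1
        assert s.lpr == 0.5
        assert s.tolerance_mm == 1.0

    def test_identical_diameters(self):
        s = summarize_patient(MetastasisSet("P1", Organ.LIVER, (10.0, 10.0, 10.0)))
        assert s.sd_diameter_mm == 0.0
        assert s.lpr == 1.0 and s.n_waves == 1

    def test_single_metastasis_flagged(self):
        s = summarize_patient(MetastasisSet("P1", Organ.LIVER, (16.0,)))
        assert s.n_total == 1
        assert s.lpr == -1.0 and s.low_n
        assert s.sd_diameter_mm is None
        assert s.tolerance_mm == 3.0
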