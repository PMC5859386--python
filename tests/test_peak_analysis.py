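"""Peak calling, merging, specificity, counting, enrichment arithmetic."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agrpipe.core_io import CoverageTrack, StrandedInterval
from agrpipe.peak_analysis import (
    LocusDefinition,
    Peak,
    PresenceMatrix,
    call_peaks,
    classify_specificity,
    count_peaks_in_region,
    enrichment_from_peaks,
    hypergeometric_enrichment,
    merge_peak_sets,
    motif_match_fraction,
    percent_matched,
)
from agrpipe.synthetic_data import DEFAULT_GROUPINGS, default_panel


def _peak(start, end, chrom="chr1", summit=None, cell=""):
    return Peak(
        StrandedInterval(chrom, start, end, "p"),
        summit if summit is not None else (start + end) // 2,
        1.0, 1e-9, 1e-9, cell,
    )


class TestCallPeaks:
    def test_flat_track_no_peaks(self):
        track = CoverageTrack("c", np.full(20000, 3.0))
        assert call_peaks(track) == []

    def test_zero_track_no_peaks(self):
        track = CoverageTrack("c", np.zeros(20000))
        assert call_peaks(track) == []

    def test_isolated_spike_gives_one_peak(self):
        # 50x background spike over 300 bp; Poisson tail p far below 1e-5
        vals = np.full(50000, 2.0)
        vals[20000:20300] = 100.0
        track = CoverageTrack("c", vals)
        peaks = call_peaks(track)
        assert len(peaks) == 1
        (pk,) = peaks
        assert pk.interval.start <= 20000 and pk.interval.end >= 20300
        assert 20000 <= pk.summit < 20300
        assert pk.q_value <= 0.01

    def test_track_shorter_than_window(self):
        assert call_peaks(CoverageTrack("c", np.ones(50)), window=200) == []

    def test_mismatched_control_length(self):
        with pytest.raises(ValueError, match="length"):
            call_peaks(
                CoverageTrack("c", np.ones(1000)),
                control=CoverageTrack("c", np.ones(999)),
            )

    def test_control_suppresses_shared_signal(self):
        vals = np.full(30000, 1.0)
        vals[10000:10300] = 40.0
        sample = CoverageTrack("c", vals.copy())
        control = CoverageTrack("c", vals.copy())
        assert call_peaks(sample, control=control) == []
        assert len(call_peaks(sample)) == 1


def oracle_clusters(intervals, min_overlap):
    """Transitive closure by pairwise union-find (quadratic oracle)."""
    n = len(intervals)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a[0] != b[0]:
                continue
            if min(a[2], b[2]) - max(a[1], b[1]) >= min_overlap:
                parent[find(j)] = find(i)
    clusters = {}
    for i in range(n):
        clusters.setdefault(find(i), set()).add(i)
    return {frozenset(v) for v in clusters.values()}


class TestMergePeakSets:
    def test_identical_sets_merge_to_one(self):
        sets = {"a": [_peak(100, 200)], "b": [_peak(100, 200)]}
        pm = merge_peak_sets(sets)
        assert len(pm.intervals) == 1
        assert pm.matrix.iloc[0].all()

    def test_disjoint_peaks_stay_separate(self):
        sets = {"a": [_peak(100, 200)], "b": [_peak(300, 400)]}
        pm = merge_peak_sets(sets)
        assert len(pm.intervals) == 2
        assert pm.matrix.values.sum() == 2

    def test_transitive_chain_merges(self):
        sets = {
            "a": [_peak(100, 250)],
            "b": [_peak(200, 350)],
            "c": [_peak(300, 450)],
        }
        pm = merge_peak_sets(sets)
        assert len(pm.intervals) == 1
        assert pm.intervals[0].start == 100 and pm.intervals[0].end == 450
        assert pm.matrix.iloc[0].all()

    @pytest.mark.parametrize("min_overlap", [1, 10])
    def test_matches_union_find_oracle(self, rng, min_overlap):
        for _ in range(5):
            entries = []
            for i in range(200):
                chrom = f"chr{int(rng.integers(2))}"
                s = int(rng.integers(0, 2000))
                entries.append((chrom, s, s + int(rng.integers(5, 80))))
            cells = [f"c{i % 4}" for i in range(len(entries))]
            sets = {}
            for (chrom, s, e), cell in zip(entries, cells):
                sets.setdefault(cell, []).append(_peak(s, e, chrom=chrom))
            pm = merge_peak_sets(sets, min_overlap)
            # compare the merged partition with the quadratic oracle by
            # matching member multisets through interval spans
            flat = [
                (pk.interval.chrom, pk.interval.start, pk.interval.end)
                for cell in sets
                for pk in sets[cell]
            ]
            expected = oracle_clusters(flat, min_overlap)
            got_spans = sorted(
                (iv.chrom, iv.start, iv.end) for iv in pm.intervals
            )
            exp_spans = sorted(
                (
                    flat[next(iter(c))][0],
                    min(flat[i][1] for i in c),
                    max(flat[i][2] for i in c),
                )
                for c in expected
            )
            assert got_spans == exp_spans


class TestClassifySpecificity:
    @pytest.fixture()
    def panel(self):
        return default_panel()

    def _pm(self, present, panel):
        row = {c: (c in present) for c in panel}
        return PresenceMatrix(
            [StrandedInterval("c", 0, 10)],
            pd.DataFrame([row], index=["c:0-10"]).astype(bool),
        )

    @pytest.mark.parametrize(
        "present,expected",
        [
            (
                {"pre-pro-B", "pro-B", "pre-B", "mature-B", "DN", "DP",
                 "mature-T", "MEF", "ES"},
                "ubiquitous",
            ),
            (
                {"pro-B", "pre-B", "DN", "DP", "mature-B", "mature-T"},
                "lymphocyte_specific",
            ),
            ({"pro-B", "pre-B"}, "B_lineage"),
            ({"DN", "DP", "mature-T"}, "T_lineage"),
            ({"pre-B"}, "stage_specific"),
            ({"DN"}, "stage_specific"),
            ({"pre-B", "MEF"}, "mixed"),
            ({"MEF", "ES"}, "mixed"),
        ],
    )
    def test_rule_table(self, panel, present, expected):
        result = classify_specificity(self._pm(present, panel), panel, DEFAULT_GROUPINGS)
        assert result.iloc[0] == expected

    def test_missing_grouping_label(self, panel):
        with pytest.raises(ValueError, match="missing"):
            classify_specificity(
                self._pm({"pre-B"}, panel), panel, {"pre-B": "B"}
            )

    @settings(derandomize=True, max_examples=120)
    @given(st.sets(st.sampled_from(sorted(DEFAULT_GROUPINGS)), min_size=1))
    def test_total_function(self, present):
        panel = default_panel()
        result = classify_specificity(
            self._pm(present, panel), panel, DEFAULT_GROUPINGS
        )
        assert result.iloc[0] in (
            "ubiquitous", "lymphocyte_specific", "B_lineage", "T_lineage",
            "stage_specific", "mixed",
        )


class TestCountPeaks:
    def test_summit_boundary_convention(self):
        region = StrandedInterval("c", 100, 200)
        at_start = _peak(90, 140, chrom="c", summit=100)
        at_end = _peak(150, 260, chrom="c", summit=200)
        assert count_peaks_in_region([at_start, at_end], region) == 1

    def test_empty(self):
        assert count_peaks_in_region([], StrandedInterval("c", 0, 10)) == 0

    def test_other_chromosome_excluded(self):
        region = StrandedInterval("c", 0, 1000)
        assert count_peaks_in_region([_peak(10, 50, chrom="other")], region) == 0


def exact_hypergeom_tail(N, K, n, k):
    """Oracle: exact rational upper tail by direct enumeration."""
    num = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    return float(Fraction(num, comb(N, n)))


class TestHypergeometric:
    def test_zero_successes_gives_one(self):
        assert hypergeometric_enrichment(10, 5, 4, 0).p_value == 1.0

    def test_small_exact_value(self):
        res = hypergeometric_enrichment(10, 5, 4, 4)
        assert res.p_value == pytest.approx(5 / 210, abs=1e-15)

    def test_matches_enumeration_on_grid(self):
        for N in (7, 13, 24):
            for K in range(N + 1):
                for n in range(0, N + 1, 3):
                    for k in range(min(K, n) + 1):
                        got = hypergeometric_enrichment(N, K, n, k).p_value
                        assert got == pytest.approx(
                            exact_hypergeom_tail(N, K, n, k), abs=1e-12
                        )

    def test_monotone_decreasing_in_k(self):
        ps = [hypergeometric_enrichment(60, 20, 30, k).p_value for k in range(21)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(10, 5, 4, 5)
        with pytest.raises(ValueError):
            hypergeometric_enrichment(10, 11, 4, 2)

    def test_binned_enrichment_counts(self):
        locus = LocusDefinition("L", "c", (1000, 3000), (1000, 2000), (2500, 3000), "right")
        peaks = [_peak(1100, 1200, chrom="c"), _peak(1500, 1600, chrom="c"),
                 _peak(5000, 5100, chrom="c")]
        res = enrichment_from_peaks(peaks, locus, {"c": 10000}, bin_size=1000)
        assert (res.population_bins, res.locus_bins) == (10, 2)
        assert (res.total_peaks, res.locus_peaks) == (2, 1)


class _FakeOriented:
    def __init__(self, call):
        self.call = call


class TestMotifMatchFraction:
    @pytest.mark.parametrize(
        "total,with_motif,expected",
        [
            (42250, 34560, 81.8),
            (121, 115, 95.0),
            (65, 50, 76.9),
            (18, 14, 77.8),
            (144, 114, 79.2),
            (5, 0, 0.0),
        ],
    )
    def test_percent_rounding(self, total, with_motif, expected):
        assert percent_matched(total, with_motif) == expected

    def test_ambiguous_counts_as_matched(self):
        ops = [_FakeOriented(c) for c in ("forward", "ambiguous", "no_motif")]
        total, with_motif, pct = motif_match_fraction(ops)
        assert (total, with_motif, pct) == (3, 2, 66.7)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            percent_matched(0, 0)
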