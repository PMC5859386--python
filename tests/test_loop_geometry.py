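"""Anchor geometry, extrusion-loop prediction, domain detection, census."""

import pytest

from agrpipe.loop_geometry import (
    AnchorPair,
    classify_pair,
    detect_flanked_domains,
    geometry_census,
    merge_anchors,
    predict_extrusion_loops,
)
from conftest import make_interval


def anchors_from_strands(strands, chrom="c", spacing=1000, width=20):
    return [
        make_interval(
            spacing * (i + 1), spacing * (i + 1) + width, s, chrom, f"a{i}"
        )
        for i, s in enumerate(strands)
    ]


def brute_force_loops(anchors):
    """Oracle: for each '+', nearest downstream '-' on the same chromosome."""
    ordered = sorted(anchors, key=lambda a: (a.chrom, a.start))
    out = []
    for i, a in enumerate(ordered):
        if a.strand != "+":
            continue
        partners = [
            (j, b)
            for j, b in enumerate(ordered[i + 1 :], start=i + 1)
            if b.chrom == a.chrom and b.strand == "-"
        ]
        if partners:
            j, b = min(partners, key=lambda t: t[1].start)
            out.append((a.start, b.start, j - i - 1))
    return out


def brute_force_census(anchors):
    counts = {"convergent": 0, "tandem": 0, "divergent": 0}
    for i in range(len(anchors)):
        for j in range(len(anchors)):
            a, b = anchors[i], anchors[j]
            if a.chrom != b.chrom or a.start >= b.start:
                continue
            if a.strand == b.strand:
                counts["tandem"] += 1
            elif a.strand == "+":
                counts["convergent"] += 1
            else:
                counts["divergent"] += 1
    return counts


class TestClassifyPair:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [("+", "-", "convergent"), ("-", "+", "divergent"),
         ("+", "+", "tandem"), ("-", "-", "tandem")],
    )
    def test_geometry_table(self, s1, s2, expected):
        a = make_interval(100, 120, s1)
        b = make_interval(900, 920, s2)
        assert classify_pair(a, b).geometry == expected

    def test_argument_order_irrelevant(self):
        a = make_interval(100, 120, "+")
        b = make_interval(900, 920, "-")
        assert classify_pair(b, a).geometry == "convergent"
        assert classify_pair(b, a).left == a

    def test_unstranded_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            classify_pair(make_interval(0, 10, "."), make_interval(20, 30, "+"))

    def test_overlapping_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            classify_pair(make_interval(0, 30, "+"), make_interval(20, 50, "-"))

    def test_pair_invariant_enforced(self):
        with pytest.raises(ValueError, match="geometry"):
            AnchorPair(make_interval(0, 10, "+"), make_interval(20, 30, "+"), "convergent")


class TestPredictExtrusionLoops:
    def test_single_convergent_pair(self):
        loops = predict_extrusion_loops(anchors_from_strands(["+", "-"]))
        assert len(loops) == 1
        assert loops[0].geometry == "convergent"

    def test_all_forward_array_yields_no_internal_loops(self):
        # superanchor configuration: a forward array loops only to anchors
        # beyond its own end, never within itself
        assert predict_extrusion_loops(anchors_from_strands(["+"] * 12)) == []

    def test_forward_array_with_terminal_reverse_cluster(self):
        loops = predict_extrusion_loops(anchors_from_strands(["+"] * 5 + ["-"]))
        assert len(loops) == 5
        assert all(lp.right.start == 6000 for lp in loops)

    def test_two_plus_share_nearest_minus(self):
        loops = predict_extrusion_loops(anchors_from_strands(["+", "+", "-", "-"]))
        assert [(lp.left.name, lp.right.name) for lp in loops] == [
            ("a0", "a2"), ("a1", "a2"),
        ]
        assert [lp.intervening for lp in loops] == [1, 0]

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 60))
            strands = ["+" if rng.random() < 0.5 else "-" for _ in range(n)]
            anchors = anchors_from_strands(strands, spacing=50, width=10)
            got = [
                (lp.left.start, lp.right.start, lp.intervening)
                for lp in predict_extrusion_loops(anchors)
            ]
            assert got == brute_force_loops(anchors)

    def test_translation_invariance(self):
        strands = ["+", "-", "+", "+", "-"]
        base = anchors_from_strands(strands)
        shifted = [
            make_interval(a.start + 5000, a.end + 5000, a.strand, a.chrom, a.name)
            for a in base
        ]
        pairs_base = [
            (lp.left.name, lp.right.name) for lp in predict_extrusion_loops(base)
        ]
        pairs_shift = [
            (lp.left.name, lp.right.name) for lp in predict_extrusion_loops(shifted)
        ]
        assert pairs_base == pairs_shift

    def test_mirroring_equals_mirrored_rule(self, rng):
        """Reflecting coordinates and complementing strands turns the
        forward rule (each "+" to nearest downstream "-") into its mirror
        (each "-" to nearest upstream "+")."""
        span = 10000
        flip = {"+": "-", "-": "+"}
        for _ in range(20):
            n = int(rng.integers(2, 40))
            strands = ["+" if rng.random() < 0.5 else "-" for _ in range(n)]
            base = anchors_from_strands(strands, spacing=100, width=10)
            mirrored = [
                make_interval(
                    span - a.end, span - a.start, flip[a.strand], a.chrom, a.name
                )
                for a in base
            ]
            got = {
                frozenset((lp.left.name, lp.right.name))
                for lp in predict_extrusion_loops(mirrored)
            }
            # mirrored-rule oracle on the original array
            ordered = sorted(base, key=lambda a: a.start)
            expected = set()
            for j, b in enumerate(ordered):
                if b.strand != "-":
                    continue
                ups = [a for a in ordered[:j] if a.strand == "+"]
                if ups:
                    expected.add(frozenset((ups[-1].name, b.name)))
            assert got == expected


class TestMergeAnchors:
    def test_overlapping_anchors_keep_best_score(self):
        a = make_interval(100, 130, "+", score=5.0, name="weak")
        b = make_interval(120, 150, "-", score=9.0, name="strong")
        (kept,) = merge_anchors([a, b])
        assert kept.name == "strong"


class TestDetectFlankedDomains:
    def test_convergent_flanks_supported(self):
        cluster = make_interval(2000, 3000, ".", name="cl")
        anchors = [make_interval(1500, 1520, "+"), make_interval(3500, 3520, "-")]
        (call,) = detect_flanked_domains([cluster], anchors)
        assert call.supported

    def test_tandem_flanks_unsupported(self):
        cluster = make_interval(2000, 3000, ".")
        anchors = [make_interval(1500, 1520, "+"), make_interval(3500, 3520, "+")]
        (call,) = detect_flanked_domains([cluster], anchors)
        assert not call.supported

    def test_multiple_upstream_candidates(self):
        # two forward anchors upstream, one reverse downstream: both are
        # convergent candidate flanks of the same cluster
        cluster = make_interval(2000, 3000, ".")
        anchors = [
            make_interval(1000, 1020, "+"),
            make_interval(1500, 1520, "+"),
            make_interval(3500, 3520, "-"),
        ]
        calls = detect_flanked_domains([cluster], anchors)
        assert len(calls) == 2
        assert all(c.supported for c in calls)
        assert {c.upstream.start for c in calls} == {1000, 1500}

    def test_missing_flank_yields_no_call(self):
        cluster = make_interval(2000, 3000, ".")
        anchors = [make_interval(1500, 1520, "+")]
        assert detect_flanked_domains([cluster], anchors) == []


class TestGeometryCensus:
    def test_two_anchor_example(self):
        census = geometry_census(anchors_from_strands(["+", "-"]))
        assert census["all_pairs"]["convergent"] == 1
        assert census["all_pairs"]["tandem"] == 0
        assert census["all_pairs"]["divergent"] == 0

    def test_all_forward_pairs_tandem(self):
        n = 9
        census = geometry_census(anchors_from_strands(["+"] * n))
        assert census["all_pairs"]["tandem"] == n * (n - 1) // 2
        assert census["predicted_loops"]["total"] == 0

    def test_matches_brute_force(self, rng):
        strands = ["+" if rng.random() < 0.5 else "-" for _ in range(50)]
        anchors = anchors_from_strands(strands, spacing=37, width=9)
        census = geometry_census(anchors)
        expected = brute_force_census(anchors)
        for g, count in expected.items():
            assert census["all_pairs"][g] == count

    def test_fractions_sum_to_one(self, rng):
        strands = ["+" if rng.random() < 0.4 else "-" for _ in range(20)]
        census = geometry_census(anchors_from_strands(strands))
        total = sum(
            census["all_pairs"][f"{g}_fraction"]
            for g in ("convergent", "tandem", "divergent")
        )
        assert total == pytest.approx(1.0)

    def test_fewer_than_two_anchors_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            geometry_census(anchors_from_strands(["+"]))
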