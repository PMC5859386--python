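"""Anchor-pair geometry and convergent-loop prediction.

Under loop extrusion, cohesin enlarges a chromatin loop until it reaches
two CTCF sites facing each other, so stable loops form preferentially
between convergent anchors.  This module classifies ordered anchor pairs
as convergent / tandem / divergent, predicts loops under a fully-blocking
nearest-convergent-partner rule, finds gene clusters flanked by inward-
pointing anchors, and produces exhaustive pair censuses.  The loop rule
is a model: real loci document tandem-loop exceptions, so intervening-
anchor counts are reported to let users relax blocking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core_io import StrandedInterval


def _require_oriented(iv: StrandedInterval) -> None:
    if iv.strand not in ("+", "-"):
        raise ValueError(
            f"anchor {iv.name} at {iv.chrom}:{iv.start} has strand '.'; "
            "orient or exclude it first"
        )


@dataclass(frozen=True)
class AnchorPair:
    """Two anchors ordered by coordinate, with their relative geometry.

    Geometry by (left strand, right strand): (+,-) convergent (facing),
    equal signs tandem, (-,+) divergent (back-to-back).
    """

    left: StrandedInterval
    right: StrandedInterval
    geometry: str
    intervening: int = 0

    def __post_init__(self) -> None:
        if self.left.start >= self.right.start:
            raise ValueError("left anchor must precede right anchor")
        expected = _geometry(self.left.strand, self.right.strand)
        if self.geometry != expected:
            raise ValueError(f"geometry must be {expected!r} for these strands")

    @property
    def span(self) -> int:
        return self.right.start - self.left.end


def _geometry(left_strand: str, right_strand: str) -> str:
    if left_strand == right_strand:
        return "tandem"
    return "convergent" if left_strand == "+" else "divergent"


def classify_pair(a: StrandedInterval, b: StrandedInterval) -> AnchorPair:
    """Order two anchors by coordinate and classify their geometry."""
    _require_oriented(a)
    _require_oriented(b)
    if a.chrom != b.chrom:
        raise ValueError("anchors must share a chromosome")
    if min(a.end, b.end) > max(a.start, b.start):
        raise ValueError("anchors must not overlap")
    left, right = (a, b) if a.start < b.start else (b, a)
    return AnchorPair(left, right, _geometry(left.strand, right.strand))


def merge_anchors(anchors: Sequence[StrandedInterval]) -> list[StrandedInterval]:
    """Collapse overlapping anchors, keeping the best-scoring one."""
    for a in anchors:
        _require_oriented(a)
    ordered = sorted(anchors, key=lambda a: (a.chrom, a.start, a.end))
    out: list[StrandedInterval] = []
    for a in ordered:
        if out and out[-1].chrom == a.chrom and a.start < out[-1].end:
            if a.score > out[-1].score:
                out[-1] = a
        else:
            out.append(a)
    return out


def predict_extrusion_loops(anchors: Sequence[StrandedInterval]) -> list[AnchorPair]:
    """Loops under the nearest-convergent-partner, fully-blocking rule.

    Every "+" anchor pairs with the nearest downstream "-" anchor on its
    chromosome (if any); every predicted loop is convergent by
    construction.  ``intervening`` counts anchors strictly inside the
    loop.  An all-same-strand array therefore yields no internal loops —
    the superanchor configuration, where a forward array can only reach
    convergent partners beyond its own end.
    """
    ordered = sorted(anchors, key=lambda a: (a.chrom, a.start))
    for a in ordered:
        _require_oriented(a)
    loops: list[AnchorPair] = []
    for i, left in enumerate(ordered):
        if left.strand != "+":
            continue
        for j in range(i + 1, len(ordered)):
            right = ordered[j]
            if right.chrom != left.chrom:
                break
            if right.strand == "-":
                loops.append(
                    AnchorPair(left, right, "convergent", intervening=j - i - 1)
                )
                break
    return loops


@dataclass(frozen=True)
class DomainCall:
    """A gene cluster with its nearest flanking anchors.

    ``supported`` means the flanks are convergent around the cluster:
    upstream "+" and downstream "-", positioned to close a loop domain
    containing the cluster.
    """

    cluster: StrandedInterval
    upstream: StrandedInterval
    downstream: StrandedInterval
    supported: bool

    def __post_init__(self) -> None:
        if self.supported and not (
            self.upstream.strand == "+"
            and self.downstream.strand == "-"
            and self.upstream.end <= self.cluster.start
            and self.cluster.end <= self.downstream.start
        ):
            raise ValueError("supported call violates convergent-flank geometry")


def detect_flanked_domains(
    clusters: Sequence[StrandedInterval],
    anchors: Sequence[StrandedInterval],
) -> list[DomainCall]:
    """Find clusters flanked by convergently oriented anchors.

    For each cluster the nearest anchor strictly upstream and strictly
    downstream are located; the call is supported when that pair is
    convergent.  When several consecutive "+" anchors sit immediately
    upstream, each one is reported as a candidate convergent flank of the
    same downstream "-" anchor (nested candidate domains).  Clusters
    lacking a flank on either side yield no call.
    """
    for a in anchors:
        _require_oriented(a)
    ordered = sorted(anchors, key=lambda a: (a.chrom, a.start))
    calls: list[DomainCall] = []
    for cluster in sorted(clusters, key=lambda c: (c.chrom, c.start)):
        same = [a for a in ordered if a.chrom == cluster.chrom]
        ups = [a for a in same if a.end <= cluster.start]
        downs = [a for a in same if a.start >= cluster.end]
        if not ups or not downs:
            continue
        nearest_up, nearest_down = ups[-1], downs[0]
        convergent = nearest_up.strand == "+" and nearest_down.strand == "-"
        if convergent:
            flanks = [nearest_up]
            for a in reversed(ups[:-1]):
                if a.strand != "+":
                    break
                flanks.append(a)
            for up in flanks:
                calls.append(DomainCall(cluster, up, nearest_down, True))
        else:
            calls.append(DomainCall(cluster, nearest_up, nearest_down, False))
    return calls


def geometry_census(
    anchors: Sequence[StrandedInterval],
) -> dict[str, dict[str, float]]:
    """Convergent/tandem/divergent counts over all ordered pairs and loops.

    Returns counts and fractions both for every same-chromosome anchor
    pair (exhaustive census) and restricted to predicted extrusion loops.
    Fractions sum to 1 within each census with at least one pair.
    """
    if len(anchors) < 2:
        raise ValueError("need at least 2 anchors for a census")
    ordered = sorted(anchors, key=lambda a: (a.chrom, a.start))
    for a in ordered:
        _require_oriented(a)
    pair_counts = {"convergent": 0, "tandem": 0, "divergent": 0}
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            if ordered[i].chrom != ordered[j].chrom:
                continue
            pair_counts[_geometry(ordered[i].strand, ordered[j].strand)] += 1
    loops = predict_extrusion_loops(ordered)
    loop_counts = {"convergent": len(loops), "tandem": 0, "divergent": 0}

    def with_fractions(counts: dict[str, int]) -> dict[str, float]:
        total = sum(counts.values())
        out: dict[str, float] = dict(counts)
        out["total"] = total
        for g in ("convergent", "tandem", "divergent"):
            out[f"{g}_fraction"] = counts[g] / total if total else 0.0
        return out

    return {
        "all_pairs": with_fractions(pair_counts),
        "predicted_loops": with_fractions(loop_counts),
    }
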