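"""CTCF site orientation calling from peak sequences.

The non-palindromic CTCF motif gives every bound site a direction, which
decides which loops extrusion can form.  The procedure: scan each
confident peak against a motif library on both strands, give every hit a
sign from its strand, take the consensus sign per peak (strict majority
over hit instances), discard ambiguous ties, and emit a stranded BED of
oriented sites.  Peaks whose sequence contains no motif are reported as
``no_motif`` and also excluded from the stranded output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .core_io import (
    MotifMatrix,
    SequenceRecord,
    StrandedInterval,
    reverse_complement,
)
from .peak_analysis import LocusDefinition, Peak

OrientationCall = Literal["forward", "reverse", "ambiguous", "no_motif"]


@dataclass(frozen=True)
class MotifHit:
    """A motif instance inside a peak, in genome coordinates."""

    motif: str
    interval: StrandedInterval
    score: float

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("motif hit strand must be + or -")


@dataclass(frozen=True)
class OrientedPeak:
    """A peak with its consensus orientation call and supporting hits."""

    peak: Peak
    call: OrientationCall
    hits: tuple[MotifHit, ...]
    votes: tuple[int, int]  # (+ votes, - votes)

    def __post_init__(self) -> None:
        plus, minus = self.votes
        ok = {
            "forward": plus > minus,
            "reverse": minus > plus,
            "ambiguous": plus == minus > 0,
            "no_motif": not self.hits,
        }
        if not ok.get(self.call, False):
            raise ValueError(
                f"call {self.call!r} inconsistent with votes {self.votes}"
            )


_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def _scores(seq: str, motif: MotifMatrix) -> np.ndarray:
    """Log-odds score at every offset; N bases contribute 0 bits."""
    codes = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    L, W = len(codes), motif.length
    if L < W:
        return np.empty(0)
    lo = np.hstack([motif.log_odds, np.zeros((W, 1))])  # column 4 scores N as 0
    windows = np.lib.stride_tricks.sliding_window_view(codes, W)
    return lo[np.arange(W), windows].sum(axis=1)


def scan_peak(
    peak_seq: str,
    genome_offset: int,
    library: Sequence[MotifMatrix],
) -> list[MotifHit]:
    """All motif instances in a peak sequence, both strands.

    Minus-strand hits are scored on the reverse complement and reported
    back in genome coordinates with strand "-".  A peak shorter than
    every motif yields an empty list.
    """
    if set(peak_seq) - set("ACGTN"):
        raise ValueError("peak sequence must be over {A,C,G,T,N}")
    hits: list[MotifHit] = []
    rc = reverse_complement(peak_seq)
    L = len(peak_seq)
    for motif in library:
        for strand, seq in (("+", peak_seq), ("-", rc)):
            scores = _scores(seq, motif)
            for off in np.flatnonzero(scores >= motif.log_odds_threshold):
                start = int(off) if strand == "+" else L - int(off) - motif.length
                hits.append(
                    MotifHit(
                        motif.name,
                        StrandedInterval(
                            "peak", genome_offset + start,
                            genome_offset + start + motif.length,
                            motif.name, float(scores[off]), strand,
                        ),
                        float(scores[off]),
                    )
                )
    hits.sort(key=lambda h: (h.interval.start, h.interval.strand, h.motif))
    return hits


def collapse_hits(hits: Sequence[MotifHit]) -> list[MotifHit]:
    """Collapse overlapping same-motif same-strand hits to the best one.

    One physical site should cast one vote; without collapsing, a wide
    peak with a sloppy motif would inflate the tally.
    """
    by_group: dict[tuple[str, str], list[MotifHit]] = {}
    for h in hits:
        by_group.setdefault((h.motif, h.interval.strand), []).append(h)
    out: list[MotifHit] = []
    for group in by_group.values():
        group.sort(key=lambda h: h.interval.start)
        cluster: list[MotifHit] = []
        cluster_end = -1
        for h in group:
            if cluster and h.interval.start >= cluster_end:
                out.append(max(cluster, key=lambda x: x.score))
                cluster = []
            cluster.append(h)
            cluster_end = max(cluster_end, h.interval.end)
        if cluster:
            out.append(max(cluster, key=lambda x: x.score))
    out.sort(key=lambda h: (h.interval.start, h.interval.strand, h.motif))
    return out


def assign_orientation(
    hits: Sequence[MotifHit],
    vote_mode: str = "per_instance",
) -> tuple[OrientationCall, tuple[int, int]]:
    """Consensus sign over motif hits.

    ``per_instance`` (default): every collapsed hit votes once.
    ``per_motif``: each motif model votes once, with its best hit's
    strand.  A strict majority gives forward/reverse; a tie with at least
    one hit is ambiguous; no hits is no_motif.
    """
    if vote_mode not in ("per_instance", "per_motif"):
        raise ValueError("vote_mode must be 'per_instance' or 'per_motif'")
    voters = collapse_hits(hits)
    if vote_mode == "per_motif":
        best: dict[str, MotifHit] = {}
        for h in voters:
            if h.motif not in best or h.score > best[h.motif].score:
                best[h.motif] = h
        voters = list(best.values())
    plus = sum(1 for h in voters if h.interval.strand == "+")
    minus = len(voters) - plus
    if plus == minus == 0:
        return "no_motif", (0, 0)
    if plus == minus:
        return "ambiguous", (plus, minus)
    return ("forward" if plus > minus else "reverse"), (plus, minus)


def orient_peak_set(
    peaks: Sequence[Peak],
    genome: SequenceRecord,
    library: Sequence[MotifMatrix],
    vote_mode: str = "per_instance",
) -> list[OrientedPeak]:
    """Scan and orient every peak against the library.

    Peaks are scanned over their full called width.  The returned report
    keeps all four call classes; use :func:`stranded_intervals` for the
    BED-ready subset.
    """
    out: list[OrientedPeak] = []
    for pk in peaks:
        iv = pk.interval
        if iv.chrom != genome.id or iv.end > len(genome):
            raise ValueError(f"peak {iv} outside genome {genome.id!r}")
        hits = scan_peak(genome.seq[iv.start : iv.end], iv.start, library)
        call, votes = assign_orientation(hits, vote_mode)
        out.append(OrientedPeak(pk, call, tuple(collapse_hits(hits)), votes))
    return out


def stranded_intervals(oriented: Sequence[OrientedPeak]) -> list[StrandedInterval]:
    """BED6 records for oriented peaks; ambiguous/no_motif are discarded."""
    strand_of = {"forward": "+", "reverse": "-"}
    out = []
    for op in oriented:
        if op.call in strand_of:
            iv = op.peak.interval
            out.append(
                StrandedInterval(
                    iv.chrom, iv.start, iv.end, iv.name,
                    op.peak.height, strand_of[op.call],
                )
            )
    return out


def call_counts(oriented: Sequence[OrientedPeak]) -> dict[str, int]:
    counts = {"forward": 0, "reverse": 0, "ambiguous": 0, "no_motif": 0}
    for op in oriented:
        counts[op.call] += 1
    return counts


def orientation_relative_to_locus(
    oriented: Sequence[OrientedPeak],
    locus: LocusDefinition,
) -> tuple[list[tuple[OrientedPeak, str]], tuple[int, int]]:
    """Classify oriented peaks as pointing toward or away from the D-J-C end.

    A site points toward D-J-C when its strand agrees with the locus
    polarity: "+" with D-J-C at the right, or "-" with D-J-C at the left.
    Only forward/reverse calls are admissible; pass a pre-filtered list.
    Returns the per-peak labels plus a (toward, away) tally.
    """
    labelled: list[tuple[OrientedPeak, str]] = []
    toward = 0
    for op in oriented:
        if op.call not in ("forward", "reverse"):
            raise ValueError(
                f"peak {op.peak.interval.name} has call {op.call!r}; only "
                "forward/reverse peaks can be tallied"
            )
        iv = op.peak.interval
        if iv.chrom != locus.chrom or not (
            locus.span[0] <= iv.start and iv.end <= locus.span[1]
        ):
            raise ValueError(f"peak {iv} outside locus {locus.name!r}")
        strand = "+" if op.call == "forward" else "-"
        is_toward = (strand == "+") == (locus.polarity == "right")
        labelled.append((op, "toward_DJC" if is_toward else "away_from_DJC"))
        toward += is_toward
    return labelled, (toward, len(labelled) - toward)
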