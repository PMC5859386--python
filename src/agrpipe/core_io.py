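"""Typed genomic primitives and on-disk formats used across the pipeline.

Coordinates are 0-based half-open everywhere (BED convention).  The module
houses the four core value types — :class:`StrandedInterval`,
:class:`MotifMatrix`, :class:`SequenceRecord`, :class:`CoverageTrack` — and
readers/writers for BED, FASTA, bedGraph and a HOMER-style motif-library
text dialect (see ``docs/methods.md`` for the grammar).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC nucleotide codes mapped to the set of concrete bases they allow.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """A malformed line in an on-disk file; message names the line number."""


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string over {A,C,G,T,N}.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    if set(seq) - set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"invalid DNA characters: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class StrandedInterval:
    """A genomic interval (0-based half-open) with optional strand.

    The universal currency of peaks, motif hits and locus spans.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """Half-open membership test for a point position."""
        return self.start <= pos < self.end


def read_intervals(path: str | Path) -> list[StrandedInterval]:
    """Read BED3–BED6 records, preserving file order.

    Missing strand defaults to ``"."``.  Malformed lines raise
    :class:`ParseError` naming the offending line number.
    """
    out: list[StrandedInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if not 3 <= len(fields) <= 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 3-6 columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else "."
                score = float(fields[4]) if len(fields) > 4 else 0.0
                strand = fields[5] if len(fields) > 5 else "."
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            try:
                out.append(StrandedInterval(chrom, start, end, name, score, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_intervals(intervals: Iterable[StrandedInterval], path: str | Path) -> None:
    """Write intervals as 6-column BED; round-trips with :func:`read_intervals`."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = f"{iv.score:g}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
            )


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise ValueError("empty sequence")
        extra = set(self.seq) - set("ACGTN")
        if extra:
            raise ValueError(f"invalid characters in sequence: {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    return [
        SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


@dataclass
class CoverageTrack:
    """Per-base read coverage over one chromosome.

    ``normalization`` records whether values are raw depths or scaled to
    one million reads.
    """

    chrom: str
    values: np.ndarray
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be a 1-D array")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be >= 0")
        if self.normalization not in ("raw", "per-1M-reads"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def __len__(self) -> int:
        return len(self.values)

    def per_million(self, total_reads: int) -> "CoverageTrack":
        """Rescale to a 1M-read library size (signal-track convention)."""
        if total_reads <= 0:
            raise ValueError("total_reads must be positive")
        return CoverageTrack(
            self.chrom, self.values * (1e6 / total_reads), "per-1M-reads"
        )


def write_bedgraph(track: CoverageTrack, path: str | Path, mode: str = "w") -> None:
    """Write a coverage track as run-length-encoded bedGraph."""
    vals = track.values
    with open(path, mode) as fh:
        if len(vals) == 0:
            return
        change = np.flatnonzero(np.diff(vals)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(vals)]))
        for s, e in zip(starts, ends):
            v = vals[s]
            if v != 0:
                fh.write(f"{track.chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: str | Path, chrom: str, length: int) -> CoverageTrack:
    vals = np.zeros(length)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            if fields[0] != chrom:
                continue
            vals[int(fields[1]) : int(fields[2])] = float(fields[3])
    return CoverageTrack(chrom, vals)


@dataclass(frozen=True)
class MotifMatrix:
    """A position-probability matrix with a log-odds detection threshold.

    ``probs`` is an L x 4 array of base probabilities over (A, C, G, T);
    every row sums to 1 and every entry is strictly positive (a zero would
    make the log-odds -inf).  ``log_odds_threshold`` is the minimal score,
    in bits against a uniform background, at which a scanned window counts
    as a hit.  ``source`` records how the motif entered the library:
    retrieved from a motif database, discovered de novo from ChIP-seq, or
    converted from an IUPAC consensus.
    """

    name: str
    probs: np.ndarray
    log_odds_threshold: float
    source: str = "database"

    _VALID_SOURCES = ("database", "discovered", "converted-consensus")

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("probs must be an L x 4 matrix with L >= 1")
        if np.any(probs <= 0):
            raise ValueError(
                f"motif {self.name!r}: zero/negative probability; "
                "apply a pseudocount before loading"
            )
        sums = probs.sum(axis=1)
        if np.any(np.abs(sums - 1) > 1e-6):
            bad = int(np.argmax(np.abs(sums - 1)))
            raise ValueError(
                f"motif {self.name!r}: row {bad} sums to {sums[bad]:.6f}, not 1"
            )
        object.__setattr__(self, "probs", probs / sums[:, None])
        if self.source not in self._VALID_SOURCES:
            raise ValueError(f"unknown motif source {self.source!r}")
        if self.log_odds_threshold > self.max_score + 1e-9:
            raise ValueError(
                f"motif {self.name!r}: threshold {self.log_odds_threshold:.3f} "
                f"exceeds maximal achievable score {self.max_score:.3f}"
            )

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """Per-position log2(p / 0.25) scoring matrix (uniform background)."""
        return np.log2(self.probs / 0.25)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        """Highest-probability base at each position."""
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def score(self, window: str) -> float:
        """Log-odds score of one window (len == motif length).

        ``N`` positions contribute 0 bits (scored as background).
        """
        if len(window) != self.length:
            raise ValueError("window length must equal motif length")
        lo = self.log_odds
        total = 0.0
        for i, base in enumerate(window):
            if base != "N":
                total += lo[i, _BASE_INDEX[base]]
        return total


def consensus_to_matrix(
    consensus: str,
    mismatches_allowed: int = 0,
    name: str | None = None,
    source: str = "converted-consensus",
) -> MotifMatrix:
    """Convert an IUPAC consensus into a probability matrix plus threshold.

    Allowed bases at each position share probability mass 0.997 (split
    equally among degenerate alternatives); disallowed bases share 0.003.
    The detection threshold is placed so that any sequence within
    ``mismatches_allowed`` mismatches of the consensus scores above it and
    any sequence with more mismatches scores below it.
    """
    if mismatches_allowed < 0:
        raise ValueError("mismatches_allowed must be >= 0")
    consensus = consensus.upper()
    probs = np.empty((len(consensus), 4))
    deltas: list[float] = []  # score drop caused by a mismatch at each position
    for i, code in enumerate(consensus):
        if code not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC code {code!r} at position {i}")
        allowed = IUPAC_CODES[code]
        k = len(allowed)
        if k == 4:
            row = np.full(4, 0.25)
        else:
            row = np.full(4, 0.003 / (4 - k))
            for b in allowed:
                row[_BASE_INDEX[b]] = 0.997 / k
        probs[i] = row
        if k < 4:  # an N position cannot mismatch
            deltas.append(math.log2((0.997 / k) / (0.003 / (4 - k))))
    matrix = MotifMatrix(
        name=name or consensus, probs=probs, log_odds_threshold=0.0, source=source
    )
    max_score = matrix.max_score
    m = mismatches_allowed
    if m >= len(deltas):
        # every sequence is within the allowance; accept all windows
        threshold = float(np.sum(matrix.log_odds.min(axis=1))) - 1.0
    else:
        deltas.sort()
        worst_accepted = max_score - sum(deltas[-m:] if m else [])
        best_rejected = max_score - sum(deltas[: m + 1])
        if not best_rejected < worst_accepted:
            raise ValueError("cannot separate mismatch classes for this consensus")
        threshold = 0.5 * (worst_accepted + best_rejected)
    return replace(matrix, log_odds_threshold=threshold)


def read_motif_library(path: str | Path) -> list[MotifMatrix]:
    """Read a HOMER-style motif library.

    Each motif: a header line ``>consensus<TAB>name<TAB>threshold[<TAB>source]``
    followed by L rows of four whitespace-separated base probabilities
    (A, C, G, T).  Motif order is preserved.
    """
    motifs: list[MotifMatrix] = []
    header: tuple[str, float, str] | None = None
    rows: list[list[float]] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        if not rows:
            raise ParseError(f"{path}:{header_line}: motif has no probability rows")
        name, threshold, source = header
        try:
            motifs.append(
                MotifMatrix(name, np.array(rows), threshold, source)
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{header_line}: {exc}") from exc

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                fields = line[1:].split("\t")
                if len(fields) < 3:
                    raise ParseError(
                        f"{path}:{lineno}: header needs consensus, name, threshold"
                    )
                source = fields[3] if len(fields) > 3 else "database"
                header = (fields[1], float(fields[2]), source)
                header_line = lineno
                rows = []
            else:
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ParseError(
                        f"{path}:{lineno}: expected 4 probabilities, got {len(vals)}"
                    )
                rows.append(vals)
    flush()
    return motifs


def write_motif_library(motifs: Sequence[MotifMatrix], path: str | Path) -> None:
    """Write motifs in the dialect read by :func:`read_motif_library`."""
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(
                f">{m.consensus}\t{m.name}\t{m.log_odds_threshold:.6f}\t{m.source}\n"
            )
            for row in m.probs:
                fh.write("\t".join(f"{p:.10f}" for p in row) + "\n")
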