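"""Confident peak calling, cross-cell-type merging, specificity classes,
per-locus counting and hypergeometric locus enrichment.

The caller is a deliberately simple windowed-Poisson scorer (a plumbing
stand-in for a full ChIP-seq peak caller): sliding windows are tested
against a local/global Poisson background, filtered at a point p-value
cutoff, corrected by Benjamini-Hochberg across all tested windows, and
merged into peaks.  Default thresholds follow the confident-peak
convention of FDR <= 1% with a 1e-5 point p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import CoverageTrack, StrandedInterval
from .synthetic_data import CellTypePanel, LocusSpec


@dataclass(frozen=True)
class Peak:
    """A confident peak: interval plus summit, height and significance."""

    interval: StrandedInterval
    summit: int
    height: float
    p_value: float
    q_value: float
    cell_type: str = ""

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError("summit must lie inside the peak interval")
        if self.q_value < 0:
            raise ValueError("q_value must be >= 0")


@dataclass(frozen=True)
class LocusDefinition:
    """An AgR-like locus: full span, V and D-J-C sub-regions, polarity."""

    name: str
    chrom: str
    span: tuple[int, int]
    v_region: tuple[int, int]
    djc_region: tuple[int, int]
    polarity: str

    def __post_init__(self) -> None:
        if self.polarity not in ("left", "right"):
            raise ValueError("polarity must be 'left' or 'right'")
        lo, hi = self.span
        for s, e in (self.v_region, self.djc_region):
            if not (lo <= s < e <= hi):
                raise ValueError("sub-region outside locus span")
        djc_right = self.djc_region[0] >= self.v_region[1]
        if djc_right != (self.polarity == "right"):
            raise ValueError("polarity inconsistent with sub-region order")


def locus_definition_from_spec(spec: LocusSpec) -> LocusDefinition:
    return LocusDefinition(
        spec.name, spec.name, (0, spec.length),
        spec.v_region, spec.djc_region, spec.polarity,
    )


# ---------------------------------------------------------------------------
# Peak calling

def call_peaks(
    sample: CoverageTrack,
    control: CoverageTrack | None = None,
    window: int = 200,
    fdr_max: float = 0.01,
    p_max: float = 1e-5,
    frag_len: int = 147,
    local_bg: int = 10_000,
    cell_type: str = "",
) -> list[Peak]:
    """Call enriched peaks from a fragment-extended coverage track.

    Windows of ``window`` bp (half-window step) are converted to
    fragment-equivalent counts (window coverage sum / frag_len) and scored
    against a Poisson null whose rate is the maximum of the track's global
    mean, its local ``local_bg`` mean, and — when a control is given —
    the control's global, local and window-scale means; the multi-scale
    maximum guards against broad enrichment inflating calls.  Windows passing ``p_max`` are
    merged when they overlap; a merged peak keeps the best window p and
    BH q (computed across all tested windows) and is reported when
    q <= ``fdr_max``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if control is not None and len(control) != len(sample):
        raise ValueError("sample and control tracks differ in length")
    vals = sample.values
    L = len(vals)
    if L < window:
        return []
    step = max(1, window // 2)
    starts = np.arange(0, L - window + 1, step)

    csum = np.concatenate(([0.0], np.cumsum(vals)))
    win_sums = csum[starts + window] - csum[starts]
    counts = np.floor(win_sums / frag_len)

    def local_mean(track_vals: np.ndarray) -> np.ndarray:
        c = np.concatenate(([0.0], np.cumsum(track_vals)))
        lo = np.clip(starts + window // 2 - local_bg // 2, 0, L)
        hi = np.clip(starts + window // 2 + local_bg // 2, 0, L)
        return (c[hi] - c[lo]) / np.maximum(hi - lo, 1)

    rate = np.maximum(float(vals.mean()), local_mean(vals))
    if control is not None:
        cvals = control.values
        csum = np.concatenate(([0.0], np.cumsum(cvals)))
        control_window = (csum[starts + window] - csum[starts]) / window
        rate = np.maximum(rate, float(cvals.mean()))
        rate = np.maximum(rate, local_mean(cvals))
        rate = np.maximum(rate, control_window)
    mu = rate * window / frag_len
    pvals = stats.poisson.sf(counts - 1, np.maximum(mu, 1e-12))
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")

    order = np.flatnonzero(pvals <= p_max)
    peaks: list[Peak] = []
    i = 0
    while i < len(order):
        j = i
        s = starts[order[i]]
        e = s + window
        best_p, best_q = pvals[order[i]], qvals[order[i]]
        while j + 1 < len(order) and starts[order[j + 1]] < e:
            j += 1
            e = starts[order[j]] + window
            best_p = min(best_p, pvals[order[j]])
            best_q = min(best_q, qvals[order[j]])
        if best_q <= fdr_max:
            summit = s + int(np.argmax(vals[s:e]))
            peaks.append(
                Peak(
                    StrandedInterval(
                        sample.chrom, int(s), int(e),
                        f"peak_{len(peaks) + 1}", 0.0, ".",
                    ),
                    summit, float(vals[summit]),
                    float(best_p), float(best_q), cell_type,
                )
            )
        i = j + 1
    return peaks


# ---------------------------------------------------------------------------
# Cross-cell-type merging and specificity

@dataclass
class PresenceMatrix:
    """Merged reference intervals x cell types -> present/absent."""

    intervals: list[StrandedInterval]
    matrix: pd.DataFrame  # index aligned with intervals, bool columns per cell type

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.matrix):
            raise ValueError("interval list and matrix rows differ")
        if len(self.matrix) and not self.matrix.any(axis=1).all():
            raise ValueError("every merged interval must be present somewhere")


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def merge_peak_sets(
    peak_sets: Mapping[str, Sequence[Peak]],
    min_overlap: int = 1,
) -> PresenceMatrix:
    """Cluster peaks across cell types by literal overlap.

    Two peaks sharing >= ``min_overlap`` bp are linked; the transitive
    closure of links defines merged reference intervals (cluster spans).
    A cell type is "present" at a merged interval when it contributed at
    least one peak to the cluster.
    """
    cells = list(peak_sets)
    entries = [
        (pk.interval.chrom, pk.interval.start, pk.interval.end, cell)
        for cell in cells
        for pk in peak_sets[cell]
    ]
    if not entries:
        return PresenceMatrix([], pd.DataFrame(columns=cells, dtype=bool))
    entries.sort(key=lambda t: (t[0], t[1], t[2]))
    uf = _UnionFind(len(entries))
    active: list[int] = []
    prev_chrom = None
    for i, (chrom, start, end, _cell) in enumerate(entries):
        if chrom != prev_chrom:
            active, prev_chrom = [], chrom
        active = [j for j in active if entries[j][2] - start >= min_overlap]
        for j in active:
            if min(entries[j][2], end) - start >= min_overlap:
                uf.union(i, j)
        active.append(i)

    clusters: dict[int, list[int]] = {}
    for i in range(len(entries)):
        clusters.setdefault(uf.find(i), []).append(i)

    intervals: list[StrandedInterval] = []
    rows: list[dict[str, bool]] = []
    for members in sorted(
        clusters.values(), key=lambda ms: (entries[ms[0]][0], entries[ms[0]][1])
    ):
        chrom = entries[members[0]][0]
        start = min(entries[m][1] for m in members)
        end = max(entries[m][2] for m in members)
        present = {cell: False for cell in cells}
        for m in members:
            present[entries[m][3]] = True
        intervals.append(
            StrandedInterval(chrom, start, end, f"merged_{len(intervals) + 1}")
        )
        rows.append(present)
    matrix = pd.DataFrame(
        rows, index=[f"{iv.chrom}:{iv.start}-{iv.end}" for iv in intervals]
    ).astype(bool)
    return PresenceMatrix(intervals, matrix)


SPECIFICITY_CLASSES = (
    "ubiquitous", "lymphocyte_specific", "B_lineage", "T_lineage",
    "stage_specific", "mixed",
)


def classify_specificity(
    presence: PresenceMatrix,
    panel: CellTypePanel,
    groupings: Mapping[str, str],
) -> pd.Series:
    """Assign each merged interval one cross-cell-type specificity class.

    Classes, in precedence order: ``ubiquitous`` (present in every panel
    label, non-lymphoid included), ``lymphocyte_specific`` (both B and T
    lineages but no non-lymphoid), ``B_lineage``/``T_lineage`` (two or
    more labels of a single lymphoid lineage, nothing else),
    ``stage_specific`` (exactly one lymphoid label), and ``mixed`` for
    every remaining pattern — a total function over presence patterns.
    """
    missing = [c for c in panel if c not in groupings]
    if missing:
        raise ValueError(f"labels missing from groupings: {missing}")
    b = {c for c in panel if groupings[c] == "B"}
    t = {c for c in panel if groupings[c] == "T"}
    nl = {c for c in panel if groupings[c] not in ("B", "T")}

    def classify(row: pd.Series) -> str:
        present = {c for c in panel if row.get(c, False)}
        if present == set(panel.labels):
            return "ubiquitous"
        if not (present & nl):
            has_b, has_t = bool(present & b), bool(present & t)
            if has_b and has_t:
                return "lymphocyte_specific"
            if len(present) >= 2:
                return "B_lineage" if has_b else "T_lineage"
            if len(present) == 1:
                return "stage_specific"
        return "mixed"

    return presence.matrix.apply(classify, axis=1)


# ---------------------------------------------------------------------------
# Counting and enrichment

def count_peaks_in_region(
    peaks: Iterable[Peak], region: StrandedInterval
) -> int:
    """Number of peaks whose summit lies in ``region`` (half-open)."""
    return sum(
        1
        for pk in peaks
        if pk.interval.chrom == region.chrom and region.contains(pk.summit)
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric test of peak-bearing bins concentrating in a locus.

    Urn model: ``N`` genome bins of which ``K`` lie in the locus; ``n``
    bins genome-wide contain a peak, ``k`` of them in the locus.
    ``p_value`` is the exact upper tail P(X >= k).
    """

    population_bins: int
    locus_bins: int
    total_peaks: int
    locus_peaks: int
    p_value: float

    def __post_init__(self) -> None:
        N, K, n, k = (
            self.population_bins, self.locus_bins,
            self.total_peaks, self.locus_peaks,
        )
        if not (0 <= k <= min(K, n) and K <= N and n <= N):
            raise ValueError("impossible hypergeometric counts")
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must be in (0, 1]")


def hypergeometric_enrichment(N: int, K: int, n: int, k: int) -> EnrichmentResult:
    """Exact upper-tail hypergeometric probability P(X >= k).

    Computed through the log-gamma-stable survival function, so the tail
    stays accurate far below float underflow of individual terms.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(
            f"impossible counts N={N}, K={K}, n={n}, k={k}"
        )
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(N, K, n, k, min(max(p, 5e-324), 1.0))


def enrichment_from_peaks(
    peaks: Iterable[Peak],
    locus: LocusDefinition,
    chrom_lengths: Mapping[str, int],
    bin_size: int = 1000,
) -> EnrichmentResult:
    """Bin the genome and test locus concentration of peak-bearing bins.

    Bins of ``bin_size`` bp tile every chromosome; a bin counts as a
    "peak bin" when at least one peak summit falls in it.  The urn is
    well-defined regardless of peak widths.
    """
    bins_per_chrom = {c: -(-n // bin_size) for c, n in chrom_lengths.items()}
    N = sum(bins_per_chrom.values())
    lo, hi = locus.span
    K = (hi - 1) // bin_size - lo // bin_size + 1
    peak_bins: set[tuple[str, int]] = set()
    for pk in peaks:
        peak_bins.add((pk.interval.chrom, pk.summit // bin_size))
    n = len(peak_bins)
    k = sum(
        1
        for chrom, b in peak_bins
        if chrom == locus.chrom and lo // bin_size <= b <= (hi - 1) // bin_size
    )
    return hypergeometric_enrichment(N, K, n, k)


def motif_match_fraction(oriented_peaks: Sequence) -> tuple[int, int, float]:
    """(total, with >= 1 motif, percent to one decimal) over oriented peaks.

    A peak counts as matched when its orientation call is anything but
    ``no_motif`` — an ambiguous peak did contain motifs.
    """
    total = len(oriented_peaks)
    with_motif = sum(1 for op in oriented_peaks if op.call != "no_motif")
    return total, with_motif, percent_matched(total, with_motif)


def percent_matched(total: int, with_motif: int) -> float:
    """Percentage of peaks with at least one motif, rounded to 1 decimal."""
    if total == 0:
        raise ValueError("total must be positive")
    return round(100.0 * with_motif / total, 1)
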