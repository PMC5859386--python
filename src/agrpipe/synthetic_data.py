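"""Synthetic antigen-receptor-like loci with planted ground truth.

Generates locus sequences with oriented CTCF-like motif instances, a
per-cell-type occupancy model (peak height proportional to the fraction
of cells bound), an optional near-identical segmental duplication, and
simulated ChIP-seq reads — everything the downstream pipeline consumes,
with the planted truth retained for recovery tests.

All quantitative defaults are illustrative: real AgR loci span hundreds
of kb to Mb; the default panel scales each locus down to tens of kb while
preserving the qualitative architecture (site density, strand design,
occupancy contrasts, triplication).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_io import (
    BASES,
    CoverageTrack,
    MotifMatrix,
    SequenceRecord,
    StrandedInterval,
    consensus_to_matrix,
    reverse_complement,
)

# ---------------------------------------------------------------------------
# Cell-type panel

#: The nine cell states compared throughout: four B-lineage stages, three
#: T-lineage stages, and two non-lymphoid controls.
DEFAULT_PANEL_LABELS = (
    "pre-pro-B", "pro-B", "pre-B", "mature-B",
    "DN", "DP", "mature-T",
    "MEF", "ES",
)

DEFAULT_GROUPINGS = {
    "pre-pro-B": "B", "pro-B": "B", "pre-B": "B", "mature-B": "B",
    "DN": "T", "DP": "T", "mature-T": "T",
    "MEF": "non-lymphoid", "ES": "non-lymphoid",
}


@dataclass(frozen=True)
class CellTypePanel:
    """An ordered set of unique cell-type labels."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("panel labels must be unique")

    def __iter__(self):
        return iter(self.labels)

    def __len__(self) -> int:
        return len(self.labels)


def default_panel() -> CellTypePanel:
    return CellTypePanel(DEFAULT_PANEL_LABELS)


# ---------------------------------------------------------------------------
# Locus specification

@dataclass(frozen=True)
class PlantedSite:
    """A motif instance to write into the locus sequence."""

    position: int
    strand: str
    motif: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("planted site strand must be + or -")


@dataclass(frozen=True)
class Duplication:
    """A template segment cloned ``n_copies`` times back-to-back.

    Copy ``i`` occupies ``[start + i*len, start + (i+1)*len)``; copy 0 is
    the template itself.  ``divergence`` is the per-base substitution rate
    applied to the non-template copies (planted-site footprints are kept
    intact so the copied sites remain exact motif instances).
    """

    start: int
    end: int
    n_copies: int
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("duplication template must be non-empty")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must be in [0, 1)")

    @property
    def template_length(self) -> int:
        return self.end - self.start

    @property
    def block_end(self) -> int:
        return self.start + self.n_copies * self.template_length


@dataclass(frozen=True)
class LocusSpec:
    """An AgR-like locus blueprint.

    ``polarity`` states which genomic end holds the D-J-C cluster, so
    "toward D-J-C" is well-defined for orientation tallies.  ``occupancy``
    maps cell type -> planted-site position -> probability that the site
    is bound in a cell of that type (peak height scales with it).
    """

    name: str
    length: int
    v_region: tuple[int, int]
    djc_region: tuple[int, int]
    polarity: str
    planted_sites: tuple[PlantedSite, ...]
    occupancy: dict[str, dict[int, float]]
    duplication: Optional[Duplication] = None

    def __post_init__(self) -> None:
        if self.polarity not in ("left", "right"):
            raise ValueError("polarity must be 'left' or 'right'")
        for lo, hi in (self.v_region, self.djc_region):
            if not (0 <= lo < hi <= self.length):
                raise ValueError("sub-region outside locus")
        v, d = self.v_region, self.djc_region
        if not (v[1] <= d[0] or d[1] <= v[0]):
            raise ValueError("v_region and djc_region must be disjoint")
        djc_right = d[0] >= v[1]
        if djc_right != (self.polarity == "right"):
            raise ValueError("polarity inconsistent with sub-region order")
        for site in self.planted_sites:
            if not 0 <= site.position < self.length:
                raise ValueError(f"planted site at {site.position} outside locus")
        for cell, probs in self.occupancy.items():
            for pos, p in probs.items():
                if not 0 <= p <= 1:
                    raise ValueError(
                        f"occupancy[{cell}][{pos}] = {p} outside [0, 1]"
                    )


@dataclass
class SimTruth:
    """Planted ground truth of one synthetic locus."""

    spec: LocusSpec
    genome: SequenceRecord
    sites: list[StrandedInterval]
    duplication_map: list[tuple[int, int]]
    occupancy: dict[str, dict[int, float]]
    seed: int

    @property
    def chrom(self) -> str:
        return self.genome.id


# ---------------------------------------------------------------------------
# Default CTCF-like motif library (synthetic stand-in)

def _soften(consensus: str, rng_free: Sequence[int] = ()) -> np.ndarray:
    """Probability matrix with an 0.85 dominant base per position.

    Positions listed in ``rng_free`` are made half-degenerate (0.40/0.40
    split between the consensus base and its transition partner).
    """
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    probs = np.empty((len(consensus), 4))
    for i, base in enumerate(consensus):
        row = np.full(4, 0.05)
        if i in rng_free:
            row = np.full(4, 0.10)
            row["ACGT".index(base)] = 0.40
            row["ACGT".index(transition[base])] = 0.40
        else:
            row["ACGT".index(base)] = 0.85
        probs[i] = row
    return probs


def _discovered(name: str, consensus: str, soft: Sequence[int]) -> MotifMatrix:
    probs = _soften(consensus, soft)
    m = MotifMatrix(name, probs, log_odds_threshold=0.0, source="discovered")
    return MotifMatrix(name, probs, 0.80 * m.max_score, source="discovered")


def default_ctcf_library() -> list[MotifMatrix]:
    """A synthetic nine-entry CTCF-like motif library.

    Mirrors the common design of CTCF orientation studies: five
    database-style consensus motifs (converted to matrices with a
    zero-mismatch detection threshold) plus four discovered-style
    probability matrices with a 80%-of-maximum threshold.  The entries are
    invented stand-ins — non-palindromic, GC-rich, 14 bp — not estimates
    of any published PWM.
    """
    database = [
        ("ctcf_core", "CCGCGNGGNGGCAG"),
        ("ctcf_var1", "CCACCAGGTGGCAG"),
        ("ctcf_var2", "CCGCCAGGGGGCGC"),
        ("ctcf_var3", "TGGCCACCAGGGGG"),
        ("ctcf_var4", "CCACTAGATGGCAC"),
    ]
    lib = [
        consensus_to_matrix(cons, 0, name=name, source="database")
        for name, cons in database
    ]
    lib.append(_discovered("chip_known_1", "TGGCGCCAGCTGGT", soft=(0, 13)))
    lib.append(_discovered("chip_known_2", "CAGCAGGGGGCACT", soft=(3,)))
    lib.append(_discovered("chip_known_3", "GCCAGCAGATGGCG", soft=(7, 12)))
    lib.append(_discovered("chip_denovo_1", "ACCGCGGTGGCAGT", soft=(1,)))
    return lib


def _library_by_name(library: Sequence[MotifMatrix]) -> dict[str, MotifMatrix]:
    return {m.name: m for m in library}


def _site_realization(motif: MotifMatrix, rng: np.random.Generator) -> str:
    """A concrete sequence for a planted instance of ``motif``.

    Consensus-derived motifs sample uniformly among the allowed bases at
    each (possibly degenerate) position; discovered-style matrices plant
    their argmax consensus so the instance scores at the matrix maximum.
    """
    if motif.source == "discovered":
        return motif.consensus
    seq = []
    for row in motif.probs:
        allowed = [b for b, p in zip(BASES, row) if p > 0.1]
        seq.append(allowed[rng.integers(len(allowed))])
    return "".join(seq)


# ---------------------------------------------------------------------------
# Genome construction

def build_genome(
    spec: LocusSpec,
    seed: int,
    library: Sequence[MotifMatrix] | None = None,
) -> SimTruth:
    """Materialize a locus: background sequence, planted sites, duplication.

    Deterministic given ``(spec, seed)``.  Minus-strand sites are written
    as the reverse complement of their motif realization.  Duplication
    copies are mutated clones of the template at the stated divergence;
    mutations never fall inside planted-site footprints, so every copied
    site remains an exact motif instance and the truth map stays exact.
    """
    lib = _library_by_name(library if library is not None else default_ctcf_library())
    rng = np.random.default_rng(seed)

    seq = rng.integers(0, 4, size=spec.length)
    seq = np.frombuffer(BASES.encode(), dtype=np.uint8)[seq].copy()

    dup = spec.duplication
    if dup is not None:
        if dup.block_end > spec.length:
            raise ValueError("duplication block extends past the locus end")

    # expand planted sites: sites inside the template are cloned per copy
    expanded: list[tuple[PlantedSite, int, bool]] = []  # (site, genome pos, is_copy)
    for site in spec.planted_sites:
        motif = lib.get(site.motif)
        if motif is None:
            raise ValueError(f"planted site references unknown motif {site.motif!r}")
        s, e = site.position, site.position + motif.length
        if e > spec.length:
            raise ValueError(f"planted site at {s} overhangs the locus end")
        if dup is not None:
            in_template = dup.start <= s and e <= dup.end
            in_block = s < dup.block_end and e > dup.start
            if in_block and not in_template:
                raise ValueError(
                    f"planted site [{s},{e}) overlaps the duplication block "
                    "boundary; sites must lie inside the template or outside "
                    "the block"
                )
            if in_template:
                for i in range(dup.n_copies):
                    expanded.append((site, s + i * dup.template_length, i > 0))
                continue
        expanded.append((site, s, False))

    expanded.sort(key=lambda t: t[1])
    footprints: list[tuple[int, int]] = []
    sites: list[StrandedInterval] = []
    occupancy: dict[str, dict[int, float]] = {c: {} for c in spec.occupancy}
    prev_end = -1
    for site, pos, _is_copy in expanded:
        motif = lib[site.motif]
        s, e = pos, pos + motif.length
        if s < prev_end:
            raise ValueError(f"planted sites overlap at position {s}")
        prev_end = e
        realization = _site_realization(motif, rng)
        if site.strand == "-":
            realization = reverse_complement(realization)
        seq[s:e] = np.frombuffer(realization.encode(), dtype=np.uint8)
        footprints.append((s, e))
        sites.append(StrandedInterval(spec.name, s, e, site.motif, 0.0, site.strand))
        for cell, probs in spec.occupancy.items():
            if site.position in probs:
                occupancy[cell][s] = probs[site.position]

    duplication_map: list[tuple[int, int]] = []
    if dup is not None:
        tlen = dup.template_length
        template = seq[dup.start : dup.end].copy()
        protected = np.zeros(tlen, dtype=bool)
        for fs, fe in footprints:
            if dup.start <= fs and fe <= dup.end:
                protected[fs - dup.start : fe - dup.start] = True
        for i in range(dup.n_copies):
            cs = dup.start + i * tlen
            duplication_map.append((cs, cs + tlen))
            if i == 0:
                continue
            copy = template.copy()
            if dup.divergence > 0:
                mut = (rng.random(tlen) < dup.divergence) & ~protected
                for j in np.flatnonzero(mut):
                    alternatives = [b for b in range(4) if BASES[b] != chr(copy[j])]
                    copy[j] = ord(BASES[alternatives[rng.integers(3)]])
            seq[cs : cs + tlen] = copy

    genome = SequenceRecord(spec.name, seq.tobytes().decode())
    return SimTruth(spec, genome, sites, duplication_map, occupancy, seed)


# ---------------------------------------------------------------------------
# Read simulation

@dataclass(frozen=True)
class SimulatedRead:
    """One sequenced tag with its true origin retained."""

    id: str
    seq: str
    true_pos: int  # leftmost genome coordinate of the read
    strand: str


def simulate_reads(
    truth: SimTruth,
    cell_type: str,
    reads_per_bound_site: float = 60.0,
    read_len: int = 36,
    frag_len: int = 147,
    background_rate: float = 0.02,
    seed: int = 0,
) -> tuple[list[SimulatedRead], CoverageTrack]:
    """Simulate single-end ChIP-seq tags for one cell type.

    Each planted site emits ``Poisson(reads_per_bound_site * occupancy)``
    fragments whose midpoints are Normal(site center, frag_len/4); a
    uniform Poisson background of ``background_rate`` reads/bp covers the
    rest.  Binding is Bernoulli per cell, so aggregating over the cell
    population makes the expected peak height proportional to the fraction
    of cells bound.  The returned coverage track extends every fragment to
    ``frag_len`` and is exactly consistent with the read set.
    """
    if cell_type not in truth.occupancy:
        raise ValueError(f"unknown cell type {cell_type!r}")
    if min(reads_per_bound_site, read_len, frag_len, background_rate) < 0:
        raise ValueError("parameters must be non-negative")
    if read_len > frag_len:
        raise ValueError("read_len must not exceed frag_len")

    rng = np.random.default_rng(seed)
    genome = truth.genome.seq
    L = len(genome)
    occ = truth.occupancy[cell_type]

    frag_starts: list[int] = []
    for site in truth.sites:
        p = occ.get(site.start, 0.0)
        lam = reads_per_bound_site * p
        if lam == 0:
            continue
        n = rng.poisson(lam)
        mids = rng.normal((site.start + site.end) / 2, frag_len / 4, size=n)
        starts = np.clip(np.rint(mids - frag_len / 2).astype(int), 0, L - frag_len)
        frag_starts.extend(starts.tolist())

    n_bg = rng.poisson(background_rate * L)
    frag_starts.extend(rng.integers(0, L - frag_len + 1, size=n_bg).tolist())

    reads: list[SimulatedRead] = []
    diff = np.zeros(L + 1)
    for i, fs in enumerate(frag_starts):
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            pos = fs
            rseq = genome[pos : pos + read_len]
        else:
            pos = fs + frag_len - read_len
            rseq = reverse_complement(genome[pos : pos + read_len])
        reads.append(SimulatedRead(f"{truth.chrom}|{cell_type}|r{i}", rseq, pos, strand))
        diff[fs] += 1
        diff[fs + frag_len] -= 1

    coverage = CoverageTrack(truth.chrom, np.cumsum(diff[:-1]))
    return reads, coverage


# ---------------------------------------------------------------------------
# Default locus panel

def _v_sites(
    rng: np.random.Generator,
    start: int,
    n: int,
    spacing: int,
    strands: Sequence[str],
    motifs: Sequence[str],
    jitter: int = 200,
) -> list[PlantedSite]:
    sites = []
    for i in range(n):
        pos = start + i * spacing + int(rng.integers(-jitter, jitter + 1))
        sites.append(PlantedSite(pos, strands[i], motifs[i % len(motifs)]))
    return sites


def _occupancy(
    sites: Sequence[PlantedSite],
    djc_sites: Sequence[PlantedSite],
    v_profile: dict[str, float],
    djc_profile: dict[str, float],
) -> dict[str, dict[int, float]]:
    occ: dict[str, dict[int, float]] = {}
    for cell in DEFAULT_PANEL_LABELS:
        occ[cell] = {}
        for s in sites:
            occ[cell][s.position] = v_profile.get(cell, 0.0)
        for s in djc_sites:
            occ[cell][s.position] = djc_profile.get(cell, 0.0)
    return occ


def default_agr_panel_spec(seed: int = 0) -> tuple[list[LocusSpec], CellTypePanel]:
    """Four scaled-down AgR-like loci plus the nine-label cell panel.

    - ``igh_like``: all V-region sites on the forward strand, pointing
      toward the D-J-C end (superanchor-style design); V occupancy
      restricted to lymphocytes.
    - ``igk_like``: mixed V strands; V occupancy high only in pre-B
      (marked lineage- and stage-specificity), trace-level in pro-B,
      absent elsewhere.
    - ``trb_like``: small locus, all V sites forward, lymphocyte-restricted.
    - ``tcrad_like``: mixed strands with ~90% of V sites pointing toward
      the J-C end, plus a triplicated segment of near-identical copies.

    D-J-C-end sites are occupied in every cell type including MEF and ES.
    Deterministic given ``seed`` (the seed only jitters site spacing).
    """
    rng = np.random.default_rng(seed)
    motif_names = [m.name for m in default_ctcf_library()]
    panel = default_panel()

    lymphoid = {c: 0.85 for c in DEFAULT_PANEL_LABELS if DEFAULT_GROUPINGS[c] != "non-lymphoid"}
    everywhere = {c: 0.9 for c in DEFAULT_PANEL_LABELS}

    # --- Igh-like -----------------------------------------------------
    v = _v_sites(rng, 3000, 20, 2000, ["+"] * 20, motif_names)
    djc = [
        PlantedSite(47000, "-", "ctcf_core"),   # IGCR1-like pair
        PlantedSite(47600, "+", "ctcf_var1"),
        PlantedSite(51000, "-", "ctcf_var2"),   # 3'RR-like cluster, toward V
        PlantedSite(51600, "-", "ctcf_var3"),
        PlantedSite(52200, "-", "ctcf_core"),
    ]
    igh = LocusSpec(
        name="igh_like", length=56000,
        v_region=(2000, 42000), djc_region=(46000, 54000), polarity="right",
        planted_sites=tuple(v + djc),
        occupancy=_occupancy(v, djc, lymphoid, everywhere),
    )

    # --- Igk-like -----------------------------------------------------
    v = _v_sites(rng, 3000, 16, 2400, ["+"] * 8 + ["-"] * 8, motif_names)
    djc = [
        PlantedSite(46800, "-", "ctcf_core"),   # Cer-like pair, toward V
        PlantedSite(47400, "-", "ctcf_var1"),
        PlantedSite(48600, "-", "ctcf_var2"),   # Sis-like pair, opposed
        PlantedSite(49200, "+", "ctcf_var3"),
    ]
    igk_v_profile = {"pre-B": 0.9, "pro-B": 0.05}
    igk = LocusSpec(
        name="igk_like", length=56000,
        v_region=(2000, 42000), djc_region=(46000, 54000), polarity="right",
        planted_sites=tuple(v + djc),
        occupancy=_occupancy(v, djc, igk_v_profile, everywhere),
    )

    # --- TCRb-like ----------------------------------------------------
    v = _v_sites(rng, 3000, 8, 2100, ["+"] * 8, motif_names)
    djc = [
        PlantedSite(25000, "-", "ctcf_core"),
        PlantedSite(26500, "+", "ctcf_var1"),
    ]
    trb = LocusSpec(
        name="trb_like", length=30000,
        v_region=(2000, 20000), djc_region=(24000, 28000), polarity="right",
        planted_sites=tuple(v + djc),
        occupancy=_occupancy(v, djc, lymphoid, everywhere),
    )

    # --- TCRa/d-like with triplication --------------------------------
    # 23 sites outside the triplicated block (3 of them reversed, INT-like)
    # plus 2 forward sites inside the 6 kb template; after triplication the
    # locus carries 29 V-region sites, 26 toward the J-C end (~90%).
    out_strands = ["+"] * 23
    for idx in (5, 11, 17):
        out_strands[idx] = "-"
    v_out = _v_sites(rng, 3000, 23, 1150, out_strands, motif_names)
    v_tmpl = [
        PlantedSite(31500, "+", "ctcf_core"),
        PlantedSite(34200, "+", "ctcf_var2"),
    ]
    djc = [
        PlantedSite(53000, "-", "ctcf_core"),   # TEA-like, toward V
        PlantedSite(58000, "-", "ctcf_var1"),
        PlantedSite(59000, "+", "ctcf_var3"),   # Ea-flanking, away
    ]
    tcrad = LocusSpec(
        name="tcrad_like", length=64000,
        v_region=(2000, 48000), djc_region=(52000, 62000), polarity="right",
        planted_sites=tuple(v_out + v_tmpl + djc),
        occupancy=_occupancy(v_out + v_tmpl, djc, lymphoid, everywhere),
        duplication=Duplication(start=30000, end=36000, n_copies=3, divergence=0.005),
    )

    return [igh, igk, trb, tcrad], panel


def background_chromosome_spec(length: int = 120_000, n_sites: int = 5) -> LocusSpec:
    """A decoy chromosome giving locus-enrichment tests a genome-wide urn.

    Carries sparse, cell-type-invariant CTCF-like sites at roughly
    genome-typical density; the V/D-J-C sub-regions are placeholders (it
    is context, not an AgR locus).
    """
    spacing = length // (n_sites + 1)
    sites = [
        PlantedSite(spacing * (i + 1), "+" if i % 2 == 0 else "-", "ctcf_core")
        for i in range(n_sites)
    ]
    occupancy = {
        cell: {s.position: 0.85 for s in sites} for cell in DEFAULT_PANEL_LABELS
    }
    return LocusSpec(
        name="background_chr", length=length,
        v_region=(100, 200), djc_region=(300, 400), polarity="right",
        planted_sites=tuple(sites), occupancy=occupancy,
    )


def triplicate_locus_spec(
    n_sites_per_copy: int = 3,
    divergence: float = 0.0,
) -> LocusSpec:
    """A locus built for mapping-policy experiments.

    A 6 kb template carrying ``n_sites_per_copy`` forward sites is
    triplicated identically (or at the requested divergence); a matched
    non-duplicated control block downstream carries the same number of
    sites at the same spacing and occupancy 1.0 everywhere.
    """
    tmpl_start, tmpl_len = 8000, 6000
    spacing = tmpl_len // (n_sites_per_copy + 1)
    tmpl_sites = [
        PlantedSite(tmpl_start + (i + 1) * spacing, "+", "ctcf_core")
        for i in range(n_sites_per_copy)
    ]
    ctrl_start = tmpl_start + 3 * tmpl_len + 2000  # 28000
    ctrl_sites = [
        PlantedSite(ctrl_start + (i + 1) * spacing, "+", "ctcf_core")
        for i in range(n_sites_per_copy)
    ]
    sites = tmpl_sites + ctrl_sites
    occupancy = {"generic": {s.position: 1.0 for s in sites}}
    return LocusSpec(
        name="triplicate_locus", length=40000,
        v_region=(2000, 36000), djc_region=(37000, 39000), polarity="right",
        planted_sites=tuple(sites),
        occupancy=occupancy,
        duplication=Duplication(tmpl_start, tmpl_start + tmpl_len, 3, divergence),
    )


def control_region(spec: LocusSpec) -> tuple[int, int]:
    """The non-duplicated control block of :func:`triplicate_locus_spec`."""
    if spec.duplication is None:
        raise ValueError("spec has no duplication")
    tlen = spec.duplication.template_length
    start = spec.duplication.block_end + 2000
    return start, start + tlen
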