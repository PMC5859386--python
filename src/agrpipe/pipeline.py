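"""End-to-end orchestration: simulate -> map -> call -> orient -> classify -> loops.

One config object drives every stage; a master seed deterministically
derives per-stage seeds, so an identical config reproduces the bundle
bit-for-bit.  The bundle holds, per locus and cell type, the peak calls,
orientation calls, presence/specificity classification, per-locus count
and motif-fraction tables, enrichment tests, and loop/domain predictions,
plus a manifest recording every parameter, seed, and output checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import core_io, loop_geometry, motif_orientation, multimap, peak_analysis
from .core_io import StrandedInterval
from .synthetic_data import (
    DEFAULT_GROUPINGS,
    CellTypePanel,
    LocusSpec,
    SimTruth,
    background_chromosome_spec,
    build_genome,
    default_agr_panel_spec,
    default_ctcf_library,
    simulate_reads,
)

#: Cell type in which each default locus rearranges (drives which track is
#: used for orientation, loop and motif-fraction summaries).
REARRANGING_CELL = {
    "igh_like": "pro-B",
    "igk_like": "pre-B",
    "trb_like": "DN",
    "tcrad_like": "DP",
}


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters plus the master seed.

    Defaults are the panel's study conditions; see ``docs/methods.md``
    for units and rationale.
    """

    seed: int = 0
    outdir: Optional[str] = None
    v_max: int = 2
    m_max: int = 3
    window: int = 200
    fdr_max: float = 0.01
    p_max: float = 1e-5
    min_overlap: int = 1
    bin_size: int = 1000
    reads_per_bound_site: float = 60.0
    read_len: int = 36
    frag_len: int = 147
    background_rate: float = 0.02
    vote_mode: str = "per_instance"
    weight_mode: str = "full"
    include_background: bool = True

    def __post_init__(self) -> None:
        if self.v_max < 0 or self.m_max < 1:
            raise ValueError("require v_max >= 0 and m_max >= 1")
        if not (0 < self.fdr_max <= 1 and 0 < self.p_max <= 1):
            raise ValueError("fdr_max and p_max must be in (0, 1]")
        if self.window < 1 or self.bin_size < 1 or self.min_overlap < 1:
            raise ValueError("window, bin_size and min_overlap must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class LocusBundle:
    """Everything the pipeline derived for one locus."""

    spec: LocusSpec
    truth: SimTruth
    definition: peak_analysis.LocusDefinition
    peaks: dict[str, list[peak_analysis.Peak]]
    oriented: dict[str, list[motif_orientation.OrientedPeak]]
    presence: peak_analysis.PresenceMatrix
    specificity: pd.Series
    anchors: list[StrandedInterval]
    loops: list[loop_geometry.AnchorPair]
    census: Optional[dict]
    domains: list[loop_geometry.DomainCall]
    enrichment: dict[str, peak_analysis.EnrichmentResult]


@dataclass
class PipelineResult:
    config: PipelineConfig
    panel: CellTypePanel
    loci: dict[str, LocusBundle]
    report: pd.DataFrame
    manifest: dict[str, Any]


def _derive_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def run_pipeline(
    config: PipelineConfig,
    specs: Optional[list[LocusSpec]] = None,
    panel: Optional[CellTypePanel] = None,
    write: bool = False,
) -> PipelineResult:
    """Run every stage over the locus panel.

    With no explicit ``specs``/``panel`` the default synthetic AgR panel
    is used (its design seed derived from the master seed).  ``write``
    emits the full file bundle into ``config.outdir``.
    """
    root = np.random.SeedSequence(config.seed)
    design_ss, genome_ss, reads_ss = root.spawn(3)
    if specs is None or panel is None:
        specs, panel = default_agr_panel_spec(_derive_seed(design_ss))
    library = default_ctcf_library()

    work_specs = list(specs)
    if config.include_background:
        # a decoy context chromosome so the hypergeometric urn reflects
        # genome-wide binding, not just the AgR loci themselves
        work_specs.append(background_chromosome_spec())
    chrom_lengths = {spec.name: spec.length for spec in work_specs}
    loci: dict[str, LocusBundle] = {}
    all_peaks: dict[str, list[peak_analysis.Peak]] = {c: [] for c in panel}

    genome_children = genome_ss.spawn(len(work_specs))
    reads_children = reads_ss.spawn(len(work_specs) * len(panel))

    for li, spec in enumerate(work_specs):
        is_background = spec.name not in {s.name for s in specs}
        truth = build_genome(spec, _derive_seed(genome_children[li]), library)
        definition = peak_analysis.locus_definition_from_spec(spec)
        peaks: dict[str, list[peak_analysis.Peak]] = {}
        oriented: dict[str, list[motif_orientation.OrientedPeak]] = {}
        for ci, cell in enumerate(panel):
            reads, _ = simulate_reads(
                truth, cell,
                reads_per_bound_site=config.reads_per_bound_site,
                read_len=config.read_len,
                frag_len=config.frag_len,
                background_rate=config.background_rate,
                seed=_derive_seed(reads_children[li * len(panel) + ci]),
            )
            placements = multimap.place_reads(
                reads, [truth.genome], config.v_max, config.m_max
            )
            track = multimap.coverage_from_placements(
                placements, chrom_lengths={spec.name: spec.length},
                extend_to=config.frag_len, weight_mode=config.weight_mode,
            )[spec.name]
            pk = peak_analysis.call_peaks(
                track, window=config.window, fdr_max=config.fdr_max,
                p_max=config.p_max, frag_len=config.frag_len, cell_type=cell,
            )
            peaks[cell] = pk
            all_peaks[cell].extend(pk)
            if not is_background:
                oriented[cell] = motif_orientation.orient_peak_set(
                    pk, truth.genome, library, config.vote_mode
                )
        if is_background:
            continue
        presence = peak_analysis.merge_peak_sets(peaks, config.min_overlap)
        specificity = peak_analysis.classify_specificity(
            presence, panel, DEFAULT_GROUPINGS
        )
        focus = REARRANGING_CELL.get(spec.name, next(iter(panel)))
        anchors = loop_geometry.merge_anchors(
            motif_orientation.stranded_intervals(oriented[focus])
        )
        loops = loop_geometry.predict_extrusion_loops(anchors)
        census = (
            loop_geometry.geometry_census(anchors) if len(anchors) >= 2 else None
        )
        v_end = min(spec.v_region[1], spec.djc_region[0])
        djc_start = max(spec.v_region[1], spec.djc_region[0])
        intervening = (
            [StrandedInterval(spec.name, v_end, djc_start, "v_djc_intervening")]
            if v_end < djc_start
            else []
        )
        domains = loop_geometry.detect_flanked_domains(intervening, anchors)
        loci[spec.name] = LocusBundle(
            spec, truth, definition, peaks, oriented, presence, specificity,
            anchors, loops, census, domains, enrichment={},
        )

    # locus enrichment: peak-bearing bins of each cell type, over the full
    # simulated genome, concentrating in each locus span
    for spec in specs:
        bundle = loci[spec.name]
        for cell in panel:
            bundle.enrichment[cell] = peak_analysis.enrichment_from_peaks(
                all_peaks[cell], bundle.definition, chrom_lengths, config.bin_size
            )

    report = make_report(config, panel, loci)
    manifest = _build_manifest(config, panel, loci, report)
    result = PipelineResult(config, panel, loci, report, manifest)
    if write:
        if config.outdir is None:
            raise ValueError("write=True requires config.outdir")
        write_bundle(result, Path(config.outdir))
    return result


def make_report(
    config: PipelineConfig,
    panel: CellTypePanel,
    loci: dict[str, LocusBundle],
) -> pd.DataFrame:
    """One row per (locus, cell type) with the headline statistics.

    Peak counts, V-region peak counts (the per-locus count-plot analog),
    orientation-call tallies, percent of peaks with a motif (NaN when no
    peaks were called), toward/away tallies relative to the D-J-C end,
    and the locus-enrichment p-value.
    """
    rows = []
    for name, bundle in loci.items():
        for cell in panel:
            pk = bundle.peaks[cell]
            op = bundle.oriented[cell]
            counts = motif_orientation.call_counts(op)
            if pk:
                _, _, pct = peak_analysis.motif_match_fraction(op)
            else:
                pct = float("nan")
            v_lo, v_hi = bundle.spec.v_region
            v_region = StrandedInterval(name, v_lo, v_hi, "v_region")
            orientable = [o for o in op if o.call in ("forward", "reverse")]
            _, (toward, away) = motif_orientation.orientation_relative_to_locus(
                orientable, bundle.definition
            ) if orientable else ([], (0, 0))
            rows.append(
                {
                    "locus": name,
                    "cell_type": cell,
                    "peak_count": len(pk),
                    "v_region_peak_count": peak_analysis.count_peaks_in_region(
                        pk, v_region
                    ),
                    "forward": counts["forward"],
                    "reverse": counts["reverse"],
                    "ambiguous": counts["ambiguous"],
                    "no_motif": counts["no_motif"],
                    "pct_with_motif": pct,
                    "toward_djc": toward,
                    "away_from_djc": away,
                    "enrichment_p": bundle.enrichment[cell].p_value,
                }
            )
    return pd.DataFrame(rows)


def _build_manifest(
    config: PipelineConfig,
    panel: CellTypePanel,
    loci: dict[str, LocusBundle],
    report: pd.DataFrame,
) -> dict[str, Any]:
    digest = hashlib.sha256()
    digest.update(report.to_csv(index=False).encode())
    for name in sorted(loci):
        digest.update(loci[name].truth.genome.seq.encode())
    return {
        "config": config.to_dict(),
        "panel": list(panel.labels),
        "loci": {
            name: {
                "length": b.spec.length,
                "n_planted_sites": len(b.truth.sites),
                "n_merged_intervals": len(b.presence.intervals),
                "n_loops": len(b.loops),
            }
            for name, b in loci.items()
        },
        "content_sha256": digest.hexdigest(),
    }


def write_bundle(result: PipelineResult, outdir: Path) -> None:
    """Write the full file bundle (BED/TSV/JSON) plus the manifest."""
    outdir.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}

    def emit(relpath: str, writer) -> None:
        path = outdir / relpath
        path.parent.mkdir(parents=True, exist_ok=True)
        writer(path)
        checksums[relpath] = hashlib.sha256(path.read_bytes()).hexdigest()

    for name, bundle in result.loci.items():
        emit(f"{name}/genome.fa", lambda p, b=bundle: core_io.write_fasta([b.truth.genome], p))
        emit(f"{name}/truth_sites.bed", lambda p, b=bundle: core_io.write_intervals(b.truth.sites, p))
        for cell in result.panel:
            safe = cell.replace("/", "_")
            emit(
                f"{name}/peaks_{safe}.bed",
                lambda p, b=bundle, c=cell: core_io.write_intervals(
                    [
                        dataclasses.replace(
                            pk.interval, score=pk.q_value
                        )
                        for pk in b.peaks[c]
                    ],
                    p,
                ),
            )
            emit(
                f"{name}/oriented_{safe}.bed",
                lambda p, b=bundle, c=cell: core_io.write_intervals(
                    motif_orientation.stranded_intervals(b.oriented[c]), p
                ),
            )
        emit(
            f"{name}/presence.tsv",
            lambda p, b=bundle: b.presence.matrix.to_csv(p, sep="\t"),
        )
        emit(
            f"{name}/specificity.tsv",
            lambda p, b=bundle: b.specificity.rename("class").to_csv(p, sep="\t"),
        )
        emit(
            f"{name}/loops.tsv",
            lambda p, b=bundle: pd.DataFrame(
                [
                    {
                        "chrom": lp.left.chrom,
                        "left_start": lp.left.start, "left_end": lp.left.end,
                        "right_start": lp.right.start, "right_end": lp.right.end,
                        "geometry": lp.geometry, "intervening": lp.intervening,
                    }
                    for lp in b.loops
                ]
            ).to_csv(p, sep="\t", index=False),
        )
        emit(
            f"{name}/domains.tsv",
            lambda p, b=bundle: pd.DataFrame(
                [
                    {
                        "cluster_start": d.cluster.start,
                        "cluster_end": d.cluster.end,
                        "upstream": d.upstream.start,
                        "downstream": d.downstream.start,
                        "supported": d.supported,
                    }
                    for d in b.domains
                ]
            ).to_csv(p, sep="\t", index=False),
        )
        emit(
            f"{name}/enrichment.json",
            lambda p, b=bundle: p.write_text(
                json.dumps(
                    {c: dataclasses.asdict(r) for c, r in b.enrichment.items()},
                    indent=2,
                )
            ),
        )
    emit("report.tsv", lambda p: result.report.to_csv(p, sep="\t", index=False))
    result.manifest["files_sha256"] = checksums
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
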