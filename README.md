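# agrpipe

Analysis toolkit for CTCF/cohesin binding and loop geometry in
antigen-receptor (AgR) loci — Igh, Igκ, Igλ, TCRβ, TCRα/δ, TCRγ.

AgR loci are the genome's hardest neighborhoods for ChIP-seq: huge
(0.2–3 Mb) arrays of duplicated V gene segments, binding that switches
on only in specific lymphocyte lineages and developmental stages, and a
3D architecture built from CTCF/cohesin loops whose formation depends
on the *orientation* of each bound CTCF site. `agrpipe` packages the
computational chain such a study needs, for computational
immunologists/epigenomicists who want each stage reusable and testable
in isolation:

- **Multi-mapping-aware read placement** — the report-all-best-stratum
  policy (≤ *v* mismatches, up to *m* placements; defaults *v* = 2,
  *m* = 3). Unique-only mapping (*m* = 1) leaves near-identical
  duplications (e.g. a triplicated locus segment) falsely bare; *m* = 3
  restores their coverage.
- **Confident peak calling** — windowed Poisson scoring against a
  local/global background with Benjamini–Hochberg control
  (FDR ≤ 1%, point p ≤ 1e-5).
- **Cross-cell-type specificity** — literal-overlap merging of peak
  sets into reference intervals, classified as
  ubiquitous / lymphocyte-specific / B- or T-lineage / stage-specific /
  mixed.
- **Locus enrichment** — exact hypergeometric upper tail
  P(X ≥ k) over 1 kb genome bins (N bins, K in locus, n peak-bearing,
  k in locus).
- **CTCF orientation calling** — both-strand PWM scanning of each peak
  against a nine-motif library, one vote per collapsed motif instance,
  strict-majority consensus sign; ties are discarded as ambiguous.
- **Loop geometry** — convergent/tandem/divergent pair classification,
  extrusion-loop prediction (each `+` anchor to its nearest downstream
  `−` anchor), convergently flanked gene-cluster domains, exhaustive
  geometry censuses.
- **Synthetic AgR panel** — a generator that plants oriented motif
  instances with per-cell-type occupancy (peak height ∝ fraction of
  cells bound), lymphocyte-restricted V regions vs ubiquitous
  D-J-C ends, and a triplicated segment, so the whole pipeline runs and
  is tested without any external data.

## Worked example

Run the full chain — simulate → map → call → orient → classify →
loops — over the default synthetic panel:

```python
from agrpipe import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1))
print(result.report[result.report.cell_type.isin(["pro-B", "pre-B", "MEF"])])
```

For the Igh- and Igκ-like loci this prints (excerpt):

```
   locus cell_type  peak_count  v_region_peak_count  forward  reverse  ambiguous  no_motif  pct_with_motif  toward_djc  away_from_djc  enrichment_p
igh_like     pro-B          25                   20       20        4          1         0           100.0          20              4      0.000210
igh_like     pre-B          25                   20       20        4          1         0           100.0          20              4      0.006047
igh_like       MEF           5                    0        1        4          0         0           100.0           1              4      0.539182
igk_like     pro-B           4                    0        1        3          0         0           100.0           1              3      0.999853
igk_like     pre-B          20                   16        9       11          0         0           100.0           9             11      0.104124
igk_like       MEF           4                    0        1        3          0         0           100.0           1              3      0.287766
```

Reading the numbers: the Igh analog shows the same ~25 peaks in every
lymphocyte stage but only its 5 D-J-C-end sites in fibroblasts
(`v_region_peak_count` 20 → 0), and its V-region sites all point toward
the D-J-C end (`toward_djc`). The Igκ analog is the stage-specific one:
V-region peaks appear only in pre-B (16 vs 0 in pro-B), the stage at
which that locus rearranges. Every peak contains at least one library
motif (`pct_with_motif`), and the enrichment p-value is the
hypergeometric tail of peak-bearing bins concentrating in the locus
against the simulated genome-wide background.

Loop geometry of the Igh analog (`result.loci["igh_like"]`): the
all-forward V-region array predicts **zero** internal loops — every V
anchor pairs with the reverse-oriented cluster at the locus end
(20 predicted loops, all convergent by construction; pair census
79 convergent / 196 tandem / 1 divergent). That is the superanchor
configuration: a same-orientation array can only loop to the convergent
sites beyond its own end.

The same stages are scriptable from the shell:

```bash
agrpipe simulate --seed 3 --cell-type pro-B --outdir sim
agrpipe map --reads sim/igh_like_pro-B.reads.fa --genome sim/igh_like.fa --v 2 --m 3 --out placements.tsv
agrpipe peaks --bedgraph sim/igh_like_pro-B.bedgraph --chrom igh_like --length 56000 --out peaks.bed
agrpipe orient --peaks peaks.bed --genome sim/igh_like.fa --out oriented.bed
agrpipe loops --anchors oriented.bed --out loops.tsv
agrpipe all --seed 5 --outdir bundle     # everything, plus manifest + report
```

## Layout

```
src/agrpipe/
  core_io.py            # StrandedInterval, MotifMatrix, BED/FASTA/bedGraph/motif I/O
  synthetic_data.py     # locus specs, planted-truth genomes, read simulation
  multimap.py           # best-stratum multi-placement engine, policy comparison
  peak_analysis.py      # peak caller, merging, specificity, enrichment
  motif_orientation.py  # PWM scanning, consensus-sign voting, stranded output
  loop_geometry.py      # pair geometry, extrusion loops, domains, censuses
  pipeline.py, cli.py   # orchestration, manifest, `agrpipe` CLI
docs/methods.md         # models, defaults, numerical choices, limitations
tests/                  # unit, property and end-to-end suites
```
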