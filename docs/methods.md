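# Methods

`agrpipe` models the computational chain used to characterize CTCF and
cohesin binding across antigen-receptor (AgR) loci: place ChIP-seq reads
while retaining multi-mappers over duplicated segments, call confident
peaks per cell type, classify cross-cell-type specificity, test locus
enrichment, assign each bound site an orientation from the
non-palindromic CTCF motif, and predict loop geometry under the
extrusion model. This note records the models, defaults, numerical
choices, and what the synthetic benchmark does and does not show.

## Coordinates and formats

All coordinates are 0-based half-open (BED convention) in every module;
files are plain text: BED3–BED6 for intervals, FASTA for sequences,
bedGraph (run-length encoded) for coverage, TSV for placements and
reports, JSON for enrichment/census/manifest.

### Motif library grammar

The motif-library dialect is HOMER-style text. Formally:

```
library   := motif*
motif     := header row+
header    := ">" consensus TAB name TAB threshold [TAB source] NEWLINE
row       := prob WS prob WS prob WS prob NEWLINE      ; order A, C, G, T
consensus := IUPAC+                                    ; informational
threshold := float        ; minimum detection score, bits (log2)
source    := "database" | "discovered" | "converted-consensus"
```

Every row must sum to 1 within 1e-6 and contain no zero probabilities
(a zero would make the log-odds −∞; zeros are rejected with a hint to
pseudocount rather than silently patched). Scores are log2 odds against
a uniform 0.25 background; `N` bases in scanned sequence contribute
0 bits.

### Consensus-to-matrix conversion

IUPAC consensus strings become matrices by giving the allowed bases at
each position probability mass 0.997 (split equally when degenerate)
and the disallowed bases 0.003. The exact constants are a convention;
the tested contract is the threshold placement: with a mismatch
allowance of *m*, the threshold is set halfway between the worst score
achievable with *m* mismatches and the best score achievable with
*m* + 1, so acceptance is exactly the ≤ *m*-mismatch set (verified by
exhaustive enumeration for short motifs).

## Synthetic AgR panel

The generator is the package's study-condition stand-in for real
ChIP-seq over AgR loci. Real loci span 0.17–3.2 Mb and carry 2–144
bound CTCF sites in their V regions; the default panel scales each
locus to 30–64 kb while preserving the architecture that drives the
analyses:

| locus        | length | V sites | strand design                          | V occupancy                                |
|--------------|--------|---------|----------------------------------------|--------------------------------------------|
| `igh_like`   | 56 kb  | 20      | all forward (toward D-J-C)             | 0.85 lymphoid, 0 in MEF/ES                 |
| `igk_like`   | 56 kb  | 16      | 8 forward / 8 reverse                  | 0.9 pre-B, 0.05 pro-B, 0 elsewhere         |
| `trb_like`   | 30 kb  | 8       | all forward                            | 0.85 lymphoid, 0 in MEF/ES                 |
| `tcrad_like` | 64 kb  | 29      | 26 toward / 3 away (~90%), triplicated | 0.85 lymphoid, 0 in MEF/ES                 |

D-J-C-end sites everywhere carry occupancy 0.9 in all nine cell types
(pre-pro-B, pro-B, pre-B, mature-B, DN, DP, mature-T, MEF, ES): the
D-J-C/enhancer ends of AgR loci are bound even in non-lymphoid cells,
while V-region binding is lymphocyte-restricted, and only the Igκ
analog is stage-specific. The 26/29 "toward J-C" fraction of the
TCRα/δ analog emulates the ~90% (129/144) majority seen in the real
locus; its 6 kb template is triplicated at 0.5% divergence
(near-identical copies). Occupancy values are illustrative — no
quantitative per-site occupancies exist to estimate them from.

Binding is Bernoulli per cell aggregated over the population, so a
site's expected read count is `reads_per_bound_site × occupancy` and
peak height is proportional to the fraction of cells bound — one
parameter reproduces the height-vs-occupancy relationship. Fragments
have midpoints Normal(site center, `frag_len`/4) with `frag_len = 147`
(the fragment-extension convention for single-end ChIP), reads are
36 bp, and background is a uniform Poisson process at 0.02 reads/bp.
Duplication-copy mutations are substitutions only (never inside planted
site footprints), keeping copy coordinates alignable and the truth map
exact.

What the generator does **not** emulate: fragment-size distributions,
GC and mappability bias beyond the duplication construct, sequencing
error, PCR duplicates, chromatin-accessibility confounders, or
motif-affinity-dependent occupancy. Passing recovery tests therefore
demonstrates the correctness of the pipeline's logic under its own
generative assumptions, not calibrated performance on real libraries.

### Motif library content

The shipped nine-entry library is synthetic: five "database"-style
IUPAC consensus conversions plus four "discovered"-style probability
matrices (0.85 dominant base, thresholds at 80% of maximum score),
all 14 bp, non-palindromic, GC-rich, CTCF-flavored. It mirrors the
common design of orientation studies (database motifs plus ChIP-derived
ones) but is not an estimate of any published PWM; real analyses should
supply their own library file.

## Read placement

The mapping contract is report-all-best-stratum-up-to-m: candidates are
all placements (both strands) with ≤ `v_max` mismatches (default 2),
only the minimal-mismatch stratum is kept, and a read with more than
`m_max` (default 3) best-stratum placements is discarded. The engine is
exact: pigeonhole-seeded substring search (a read split into
`v_max` + 1 segments must match one exactly) verified by full mismatch
counting, with an exact-match fast path; a brute-force all-offsets scan
is the test oracle. Ties are all reported, so placement is
deterministic. This is what rescues coverage over the triplicated
segment: at `m_max = 1` every read from an identical copy (background
included) is discarded and the copies read out at or below background;
at `m_max = 3` copy coverage is restored.

Two weighting conventions exist for coverage. `full` (default for
signal tracks) gives every retained placement weight 1, mirroring
report-all aligner semantics — an identical triplicate then shows
roughly `n_copies` times the per-site emission because each copy
receives every copy's reads. `fractional` (1/k per placement; default
in `compare_mapping_policies`) conserves one unit of mass per read,
putting duplicated copies on the same scale as a unique control region,
which is the scale on which the copy-rescue effect is quantified
(copy/control ≈ 1 at `m_max = 3`).

Identical read sequences are de-duplicated before placement in the
pipeline (the remove-duplicates-then-map convention). The policy
comparison disables de-duplication: over identical copies, sequence
identity does not imply molecular identity, and collapsing would
conflate library saturation with the placement-cap effect under
measurement.

## Peak calling

A deliberately simple windowed-Poisson caller stands in for a full
ChIP-seq caller. Windows of 200 bp (100 bp step) are converted to
fragment-equivalent counts (`floor(window coverage / frag_len)` — the
floor is conservative) and scored with an exact Poisson tail against a
rate that is the maximum of the track's global mean, its local 10 kb
mean, and, when a control track is supplied, the control's global,
local, and window-scale means. Windows passing the point cutoff
(p ≤ 1e-5) merge into peaks when they overlap; each peak keeps its best
window p and Benjamini–Hochberg q (computed across all tested windows
of the track, i.e. per sample, not across cell types) and is reported
at q ≤ 0.01 — the confident-peak convention of FDR ≤ 1% with the 1e-5
point p-value. On pure-background tracks the fraction of replicates
producing any call is well under 3× the nominal FDR (calibration test,
200 replicates). Not implemented: model building, lambda sweeping,
broad-peak modes.

## Merging, specificity, counting, enrichment

Peak sets from different cell types merge by literal overlap (≥ 1 bp by
default, configurable): the transitive closure of pairwise overlaps
defines merged reference intervals, and a cell type is present where it
contributed a peak. A quadratic union-find is the test oracle for the
sweep implementation.

Specificity classes are assigned in precedence order — `ubiquitous`
(every label), `lymphocyte_specific` (no non-lymphoid, both B and T
represented), `B_lineage`/`T_lineage` (≥ 2 labels of one lymphoid
lineage, nothing else), `stage_specific` (exactly one lymphoid label),
`mixed` (everything else) — a total function over presence patterns.
The precedence order and the ≥ 2-label lineage rule are design choices;
the categories themselves are narrative in origin and a single-label
pattern is deliberately read as stage- rather than lineage-restricted.

Per-locus peak counts use summit-in-region membership (half-open), so a
peak belongs to exactly one region.

Locus enrichment uses a binned hypergeometric urn: the genome is tiled
into 1 kb bins (configurable), N = all bins, K = locus bins, n = bins
containing ≥ 1 peak summit, k = such bins in the locus; the p-value is
the exact upper tail via the log-gamma-stable survival function
(scipy), which matches exact integer enumeration to < 1e-12 on all urns
with N ≤ 60. Bins (rather than peaks or base pairs) make the urn
well-defined regardless of peak width. The pipeline adds a 120 kb decoy
background chromosome with sparse, cell-invariant sites so that "locus
vs genome-wide" has a population to be enriched against; without it the
simulated genome is nothing but AgR loci and the test is vacuous.

## Orientation calling

Each confident peak is scanned over its full called width against the
library on both strands (minus-strand hits scored on the reverse
complement, reported in genome coordinates). Overlapping hits of the
same motif on the same strand collapse to the best-scoring instance —
one physical site, one vote. The consensus sign is a strict majority
over hit instances: majority `+` → forward, majority `−` → reverse,
tie with hits → ambiguous (discarded from stranded output), no hits →
no_motif. Majority voting is the weakest reading of "consensus"
consistent with discarding ambiguous cases; a per-motif-model voting
mode (`vote_mode="per_motif"`) is provided since the instance-vs-model
question is genuinely open. Orientation relative to a locus follows its
polarity: a site points toward the D-J-C end iff its strand agrees with
the end that holds D-J-C.

On the default panel at default depth, orientation recovery is ≥ 95%
of planted sites with zero sign errors; the misses are peaks whose
vote ties because a chance opposite-strand motif lands inside the
peak — they surface as ambiguous, never as a wrong sign.

## Loop geometry

Pair geometry is determined by ordered strands: (+,−) convergent,
(−,+) divergent, equal tandem. Loop prediction uses the
nearest-convergent-partner, fully-blocking rule: every `+` anchor pairs
with the closest downstream `−` anchor; predicted loops are convergent
by construction, and the count of intervening anchors is reported so
users can relax blocking. This is a model, not a claim — documented
tandem-loop exceptions exist in real loci. Note the one-sided rule is
not mirror-symmetric (reflecting the genome turns it into
"each `−` to its nearest upstream `+`"; the test suite checks exactly
that correspondence). A same-strand array yields no internal loops: a
forward V-region array can only loop to convergent partners beyond its
end — the superanchor configuration.

Domain detection reports, for each gene cluster, its nearest strictly
up/downstream anchors; the call is supported when they converge, and a
run of consecutive `+` anchors immediately upstream yields one
candidate call each (the nested-candidate pattern of clustered light-
chain loci). Overlapping anchors are merged to the best-scoring one
before any geometry operation; unoriented anchors are excluded, never
imputed.

## Pipeline determinism and problem sizes

A master seed feeds a `SeedSequence` tree: one child per locus genome,
one per (locus, cell type) read simulation, all derived seeds < 2^31.
Identical configs produce byte-identical bundles (hash recorded in the
manifest alongside every parameter and per-file checksums). The default
run — 4 loci + decoy × 9 cell types, ~70 k reads placed — completes in
well under a minute on one core; the acceptance script's calibration
experiments (hypergeometric sweep to N = 40, 200 null replicates, 100
loop-oracle fixtures, depth-300 triplicate experiment) were sized to
keep the whole recomputation in a few minutes while leaving each
statistical check adequately powered.

## Known limitations

- The peak caller and placement engine are plumbing stand-ins: exact
  and well-calibrated on synthetic data, but not substitutes for a
  production aligner/caller on real libraries (no quality scores,
  indels, or model-based fragment-size estimation).
- Specificity classes depend on hard presence/absence; borderline
  occupancy near the caller's detection limit can flip a class.
- The enrichment urn treats bins as exchangeable; real genomes have
  mappability and accessibility structure the decoy chromosome does not
  model.
- The synthetic occupancy table is illustrative, so absolute peak
  heights and enrichment p-values from the default panel characterize
  the method, not any real locus.
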