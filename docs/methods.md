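# Methods

This note records the models, conventions and numerical choices behind
`rtscreen`, and what the synthetic validation does and does not
demonstrate.

## Screen design

The screen is a full factorial grid over four reaction parameters.
Default level series:

| factor | levels | default series | units |
|---|---|---|---|
| TSO molarity | 9 | 0.625, 1.25, 2.5, 5, 10, 20, 40, 80, 160 (2-fold) | μM |
| RTP molarity | 6 | 1, 2, 4, 8, 16, 24 (2-fold, capped at 24) | μM |
| RNA mass | 6 | 1, 10, 10², 10³, 10⁴, 10⁵ (10-fold) | pg |
| enzyme | 2 | SSIII, SSIV | — |

The RTP series end points (1–24 μM, log-spaced) admit more than one
6-point series; the doubling series capped at 24 is the package default
and is overridable in the configuration. Enumeration order is a
deterministic nested loop, enzyme outermost, so condition lists are
reproducible across runs.

Each 384-well plate covers one enzyme: 6 zones × 64 wells, one zone per
RNA mass. A zone holds the 54-member TSO×RTP grid once, plus nine no-RTP
controls (one per TSO level) and one no-RNA control. The no-RNA control's
oligo molarities are not constrained by the design; the median level of
each series is used so the choice is deterministic. Zone z owns the
columns c with ((c−1) mod 6)+1 = z — four full 16-row columns per zone,
collectible with an 8-channel pipette in two strokes per column. The
interleaving is configurable; only the member→well assignment inside a
zone is randomized, never the zone geometry.

Randomization uses one master integer seed per plate. Sub-streams (well
permutation per zone, barcode draw, per-zone barcode placement) are
derived through fixed labelled `SeedSequence` splits, so adding or
reordering a stage never perturbs another stage's draw and equal seeds
give bit-identical layouts. The 60 control positions per plate act as a
layout fingerprint; distinct seeds give distinct fingerprints with
overwhelming probability (verified for the default 8-plate screen).

Barcodes: 64 of a ≥64-entry pool (default 70 six-mers with pairwise
Hamming distance ≥ 3, generated by seeded rejection sampling) are drawn
without replacement per plate and reused across the plate's six zones —
the barcode identifies the well within a zone, the sequencing index the
zone. Per enzyme, 4 replicate plates × 6 zones use 24 indexes, giving
1536 collision-free (barcode, index) keys per sequencing pool; the index
series is reused between the two per-enzyme pools, so pools must be
demultiplexed separately.

PCR cycles scale with input so pools reach comparable coverage: the
largest RNA mass gets 18 cycles and each 10-fold dilution three more
(18/21/24/27/30/33 from 100 ng to 1 pg).

## Transfer program

Reactions are 500 nl assembled from 25 nl droplets. Every TSO/RTP/RNA
level gets its own source pre-dilution well whose stock satisfies
`stock × v / 500 = level` at a fixed per-reagent transfer volume
(mastermix 150 nl, TSO/RTP/RNA 100 nl each, water topping to 500 nl), so
quantization is exact by construction; TSO dilutions are additionally
per-barcode since the barcode is carried on that oligo. Deviating stocks
raise a quantization error naming the unreachable level rather than
rounding. Defaults for source capacity (65 μl), seeding volume (20 μl)
and dead volume (2.5 μl) are configurable; instruments differ and no
single value is canonical.

Transfer order is reagent-major (mastermix first, water last),
destination row-major within a reagent block — conventional, and
configurable in the sense that sheets are plain ordered step lists.
Simulation debits source balances sequentially; a step that would breach
dead volume is flagged and either skipped or halts the run. Verification
reconstructs each well's TSO/RTP/RNA concentration and barcode purely
from executed events and compares them to the layout; the
design→sheet→simulate→verify loop must close with zero mismatches for
any seed, and volume conservation (Σ debited = Σ delivered = 384 × 500
nl) holds exactly.

## Synthetic reads and the response model

The toy reference is one 200 kb random chromosome with 50 non-overlapping
genes (1.4–2.4 kb, ≥ 800 nt gaps, ≥ 1 kb from contig ends so promoter
windows and fragments stay in bounds), two random rRNA references drawn
independently of the genome, and a synthetic oligo set (adapter, RTP
constant region, 10-nt TSO 3′ tail ending in GGG, mimicking the
riboguanosines). Thirty copies of the TSO tail are planted directly
upstream of intra-genic, non-promoter positions; molecules starting at
those sites are strand-invasion artefacts by construction.

Per-well read classes {artefact, rrna, unmapped, genic, promoter} follow
a softmax over logits linear in log₂-transformed levels. The artefact
logit carries 0.9·log₂(RTP/TSO): raising RTP increases artefacts and a
proportional TSO increase cancels it — the diagonal pattern that
dominates real screens. Because 0.9 exceeds every other class's
coefficient on log₂ RTP (rRNA 0.35, promoter 0.15), the artefact
probability increases strictly whenever RTP doubles at fixed TSO, at
every point of the surface. rRNA shares a weaker diagonal plus a bump at
intermediate RNA mass; genic/promoter logits rise with log₂ TSO with a
mild quadratic saturation; the first-listed enzyme (SSIII-like) carries a
stronger low-RNA artefact penalty than the second. Controls substitute
small floor levels (0.05 μM RTP, 0.01 pg RNA) for the absent reagent,
pushing them into the artefact-dominated, low-yield regime. Relative
sequence yield scales as (TSO/10)^0.35 with controls at 5%, so simulated
pools show the TSO–yield correlation of real index groups.

Reads are error-free by default (an optional uniform substitution rate
exercises barcode correction): read 1 is barcode (6 nt) + UMI (8 nt) +
32 nt insert = 46 nt, the index read is 8 nt, read 2 is 21 nt. Mapped
classes carry head-to-head mate coordinates (fragment 73–349 nt) and
UMI-level PCR duplication (each new mapped read duplicates an existing
molecule of its class with probability 0.3). Promoter reads start within
[TSS, TSS+500) on the gene strand (half-open window semantics: a
position p is promoter-assigned iff −500 ≤ p − TSS < 500, a 1000-nt
window); genic reads start ≥ 500 nt from the TSS inside the gene.
Artefact reads are either oligo-on-oligo products (guaranteed to contain
a 16-mer of the oligo set) or simple repeats; rRNA reads are substrings
of the rRNA references; unmapped reads are random sequence.

What the generator does **not** emulate: sequencing errors and quality
scores by default, indels, chimeric fragments, mappability structure of a
real genome, PCR-cycle chemistry, index hopping. Passing the end-to-end
tests therefore demonstrates the correctness of the bookkeeping —
demultiplexing, classification cascade, UMI collapse, window arithmetic —
not the robustness of any classifier to real-data noise.

## QC metric conventions

- Cascade order and denominators: artefact → rRNA → properly mapped →
  otherwise unmapped, all as percentages of demultiplexed pairs (the four
  partition to 100%); promoter rate over properly mapped pairs; strand
  invasion over molecule counts; richness over gene-assigned mapped reads.
- "Properly mapped": mates on the same chromosome, facing head to head
  (forward–reverse, each 3′ end pointing at the other mate), 5′-to-5′
  distance strictly < 2 Mb. The phrase "head to head on the same strand"
  is internally tensioned in CAGE parlance — facing mates sit on opposite
  genomic strands in standard conventions — so the facing (FR)
  interpretation is adopted and the threshold is configurable.
- Artefact filter: dinucleotide Shannon entropy < 2.0 bits, or an exact
  16-mer shared with the oligo set (either strand). The entropy criterion
  applies only to mates ≥ 30 nt: a 21-nt mate has just 20 dinucleotides
  and occasionally dips under threshold on genuine genomic sequence,
  while every artefact class is still caught through the longer mate or
  the k-mer match. False-positive rate on random 32-mers is far below
  the 1% budget.
- rRNA: 21-mer containment against the reference set, both strands —
  alignment-free, exact, and adequate for abundance screening.
- UMI collapse: one molecule per distinct (chromosome, 5′ position,
  strand, UMI); support counts retained. UMI collisions merge molecules
  identically in the pipeline and in the truth accounting, so the
  comparison stays exact.
- Strand invasion: the tail-length window upstream of the molecule 5′ end
  (strand-aware) within ≤ 2 mismatches of the TSO 3′ tail (both
  configurable). Molecules too close to the contig edge are not flagged.
  Random 10-mers pass the ≤2-mismatch test at ~4·10⁻⁴ per molecule, so
  the detector slightly over-calls relative to planted truth; the
  end-to-end checks bound this excess instead of pretending it away.
- Richness: Hurlbert rarefaction to n = 10 on reads per gene (molecule
  counts are available but reads are the default, matching rarefaction on
  mapped counts). Computed via log-gamma; classes with N_i > N − n
  contribute exactly 1. Undefined (reported missing) when N < n. Gene
  assignment: the 5′ position must fall in a same-strand gene interval;
  overlap ties break by longest interval then lexicographic id.

## Aggregation

Relative yield = well count / mean count of its PCR index group (group
mean, not total, keeping yields on a ~1 scale; group means are exactly 1).
Replicate variability = mean absolute deviation from the median, divided
by the mean — "mean average difference" admits more than one reading, and
the deviation-from-median form pairs naturally with reporting medians;
the mean-pairwise-difference alternative sits behind a flag. Surfaces are
9×6 median matrices per (enzyme, RNA mass) with missing cells preserved;
contour rendering is presentation-only and never feeds numeric output.
The Pareto front (undesirable score vs discovery score, orientations
explicit) uses a sort-and-sweep; equal-score duplicates are mutually
non-dominating and all retained. Tests compare it against an O(n²)
dominance scan.

## Problem sizes used in validation

The test suite exercises one full plate at a nominal 120 pairs/well and
the acceptance script one full plate at a nominal 1000 pairs/well
(scaled by the yield factor; ~4·10⁵ pairs), plus a 10⁵-read single-well
draw for the multinomial goodness-of-fit check and 10⁵ Monte-Carlo
subsampling draws for rarefaction. These sizes give the binomial checks
comfortable power while keeping the whole validation in the minutes
range on one CPU.
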