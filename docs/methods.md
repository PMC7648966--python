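# Methods

This note documents the models, conventions and design choices behind
`circheart`, in the order the pipeline runs. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinates and data model

All internal coordinates are 0-based half-open on the forward genomic
strand (BED convention); GTF input/output converts at the boundary. A
back-splice junction is keyed by `(chrom, start, end, strand)` with
`start` = acceptor coordinate (5'-most genomic position of the circle)
and `end` = exclusive donor coordinate; `start < end` always. The
transcribed strand is the strand on which the breakpoint shows the
canonical splice signal (genomic `AG`/`GT` on `+`, `AC`/`CT` on `−`).
Circular sequences are reported 5'→3' on that strand.

## Junction calling

A simplified anchor-based caller. Reads that fail to align contiguously
(full-length exact match to either genome strand or to a spliced
transcript sequence; a `mm` knob allows genomic mismatches) are split
into terminal k-mers (k = 20 by default). Each anchor must place
*uniquely* across both strands of the genome — a k-mer equal to its own
reverse complement, or present at two loci, disqualifies the read.
Reversed orientation (the read-start anchor placing downstream of the
read-end anchor in strand-local coordinates) triggers breakpoint search:
both anchor alignments are extended toward the read interior, and among
split points explaining the whole read as two genomic segments, the
caller requires `AG` immediately 5' of the acceptor segment and `GT`
immediately 3' of the donor segment (transcribed strand). Ties are
broken by maximizing the acceptor-segment length, then the smallest
start coordinate; mismatch tolerance applies to anchor placement only,
extension is exact. Drops are silent but counted per cause
(`too_short`, `anchor_not_unique`, `anchors_discordant`,
`forward_order`, `no_breakpoint`).

Per sample, supporting reads deduplicate by exact sequence ("unique
back-spliced reads" = distinct read sequences); junctions with ≥ 2
unique reads in at least one sample are retained.

## Origin annotation

Class precedence: (1) acceptor end in an exon of one gene and donor end
in an exon of a different same-strand *adjacent* gene (no third gene
overlapping the interval between them), with the transcription-upstream
gene first → `two-gene`; (2) both ends in exons of one gene → `CDS` if
every junction-bounded exonic nucleotide is coding, `UTR` if none is,
else `UTR-CDS`; (3) inside one gene's span otherwise → `intronic`;
(4) else `intergenic`. Exon-boundary matching requires exact coordinate
equality — the generator emits exact boundaries and no tolerance window
is defined for real data here. When a junction end could belong to two
overlapping same-strand genes, the gene sharing the exact boundary wins,
else the longer exonic overlap.

Spliced sequences concatenate annotated exons in transcription order
(acceptor exon through donor exon; for two-gene circles: acceptor exon
through the upstream gene's last exon, then exon 1 through the donor
exon of the downstream gene — the read-through splicing convention the
generator also uses). Non-boundary junctions fall back to the genomic
interval on the transcribed strand. Reported "size" therefore has two
columns: spliced length where the composition is known, genomic span
otherwise.

Naming: single-gene circles are `circGENE_n` with `n` the coordinate
rank (start, then end) of the junction within its gene — reproducible,
unlike abundance- or database-derived numbering; two-gene circles are
`GENE1_e{i}:GENE2_e{j}` from the acceptor exon of the upstream gene and
the donor exon of the downstream one; intergenic circles fall back to
`circINTERGENIC_{chrom}_{start}`.

## rt-circRNA vs homology artifact

For each two-gene circle, the 50-bp flanks on each side of the
back-splice are taken from the *circular spliced sequence* (genomic
flanks would cross introns; circles shorter than 100 nt split at the
junction). Each flank is aligned against the cDNA (concatenated exons)
of both host genes with Smith–Waterman local alignment: match +1,
mismatch −2, gap −5 for the first base and −2 for each additional
(`Bio.Align.PairwiseAligner`, both query orientations). A *hit* requires
identity ≥ 0.8 over an aligned length ≥ 25. If either flank hits both
genes the circle is called `homology_artifact`; otherwise `true_rt`
(with a low-evidence flag if a flank hits neither gene — the call does
not depend on *which* single gene was hit). The thresholds are explicit
replacements for an external aligner's implicit defaults and are
configurable; relaxing them can only move calls toward
`homology_artifact` (monotonicity is tested).

## Quantification and correlation

SRPBM = back-splice read count × 10⁹ / total mapped reads; FPKM =
fragment count × 10⁹ / (union-exon length × total fragments). The
high-confidence tier keeps features with ≥ 2 reads in ≥ 4 samples of at
least one group. Library depth for every circRNA normalization is total
mapped reads (one depth notion throughout, consistent with SRPBM), not
total back-splice reads.

Host correlation: Pearson r across samples per (circRNA, host) pair and
per (circRNA, random non-host gene) pair (draws exclude the host,
seeded); the two r distributions are compared with a two-sided Wilcoxon
rank-sum test — chosen as a distribution-free test since nothing ties
the comparison to a parametric family. Zero-variance features are
excluded and reported.

## Differential expression

Counts for feature *i* are modeled NB with common dispersion φ
(variance μ + φμ²). φ is estimated by scaling counts to the mean library
size, pooling the per-feature within-group moment estimates
max(0, (s² − m)/m²) weighted by degrees of freedom, and taking the
median over features with mean ≥ 1, floored at 10⁻⁶. The exact test
conditions on t = sum_A + sum_B after library-size equalization: group
sums are NB with sizes n_g/φ and a shared success probability, and the
two-sided p is the total conditional probability of splits no more
likely than the observed one (the modal split gives p = 1 exactly; φ→0
reduces to Binomial(t, n_A/(n_A+n_B))). No tagwise shrinkage, no TMM
factors — the common-φ exact test is the minimal testable form of the
NB model, and the linear-gene track reuses it rather than pulling in a
separate GLM framework.

Fold changes use library-size-normalized group means with pseudocount
0.5 (never used in testing); the second group in sample-sheet order is
the numerator, so with controls listed first a positive log2FC means
higher in disease. Significance is asymmetric by convention: circRNAs
at raw p < 0.05 and FC > 2 (an FDR column is still emitted), linear
genes at BH-FDR < 0.05 and FC > 2. BH is the textbook step-up
q(i) = min_{j≥i} p(j)·m/j, clipped at 1.

## Sponge screening

Seed = miRNA positions 2–8. With S = reverse complement of the seed on
the target: 8mer = S+A, 7mer-m8 = S, 7mer-A1 = S[1:]+A, 6mer = S[1:].
The circular sequence is scanned with its first 7 nt appended so
junction-wrapping sites appear contiguously; start positions are
reported modulo the circle length. Each start yields at most one site,
of its most specific type (8mer > 7mer-m8 > 7mer-A1 > 6mer); overlapping
sites at different starts all count — this makes counts exactly
reproducible and rotation-invariant (tested). 6mers are excluded by
default (weakest canonical type) behind a flag. Candidates have ≥ 5
sites for at least one panel miRNA; the top tier ≥ 10. miRNA→target
lists are an input file, not predicted here.

## The synthetic fixture

The generator emulates a 5-vs-5 ribo-depleted heart RNA-seq design at
toy scale. Defaults (all in `SimConfig`): one ~240 kb chromosome, 14
genes of 8–12 exons (130–300 nt) with 150–400 nt introns and canonical
GT/AG intron signals; 100-nt single-end error-free reads
(substitution-only errors available via `error_rate`); two special
configurations — `HOMA`/`HOMB`, adjacent same-strand genes at 95%
sequence identity (the misalignment trap), and `RTUP`/`RTDN`, adjacent
same-strand genes with independent sequences (the rt source); 60
planted circRNAs (24 CDS, 3 UTR, 3 UTR-CDS, 5 intronic, 5 intergenic,
10 true rt, 10 homology-artifact two-gene circles) with per-sample
back-splice support uniform in 3–8 reads; 6 circRNAs up- and 6
down-regulated 4-fold; gene-level linear counts 80–200 reads/sample
with lognormal (σ = 0.35) sample factors, 2 genes up- and 2
down-regulated 4-fold; 8 null circRNAs coupled to their host's sample
factor; a 10-miRNA toy panel with 12 / 5 / 3 seed sites injected into
three circRNAs (one site wrapping the back-splice).

Choices worth flagging:

* **Homolog construction.** `HOMB` copies `HOMA`'s genomic span with
  substitutions whose combined rate is solved to match
  1 − `homolog_identity`, under the constraint that no run of ≥ 19
  identical bases survives. The run guard means every exonic 20-mer
  differs between the copies, so exact anchor placement stays
  unambiguous; pure i.i.d. substitution at 5% would leave ~36% of
  20-mers identical and turn detection on the trap pair into a coin
  flip. Measured exon identity lands at ~0.947 for the 0.95 target.
* **Artifact circles are planted, not emergent.** The real artifact
  arises in mismatch-tolerant aligners; an exact-match caller cannot
  misassign an anchor (identical k-mers are non-unique and dropped).
  The generator therefore plants the artifact *outcome* — two-gene
  junctions across the trap pair with junction-spanning reads — which
  is exactly the input the homology classifier must handle.
* **Junction-spanning reads overlap the junction by ≥ 20 nt on each
  side** (`min_overhang`, matching the anchor length). A read crossing
  closer to its end cannot carry two anchors on opposite sides of the
  junction and is undetectable by construction; the fixture is designed
  so planted support equals detectable support.
* **miRNA sites are written back into the genome** through the exon
  coordinate map before reads are simulated, so detection, splicing and
  scanning all see the same sequence; truth counts are frozen by a
  naive circular recount on the final sequences (independent of the
  scanner under test).
* **Read-through transcripts are not annotated**, so background
  circular reads crossing the two-gene internal splice boundary are
  unmappable by the toy aligner; they surface as `forward_order` drops
  in the caller log and never produce junctions.

What the fixture does *not* emulate: indels and quality scores,
paired-end fragments, expression dispersion calibrated to real tissue,
isoform diversity within a junction, intron-retaining circles,
repeat-driven multimapping beyond the single homolog pair. Passing
tests therefore demonstrate algorithmic correctness under clean,
controlled conditions — not performance on real libraries, where
alignment noise and annotation incompleteness dominate.

## Calibration fixtures

The NB null-calibration check uses 10,000 features with log-uniform
means in [20, 200] at φ = 0.1, 5 vs 5 samples: means of at least ~20
keep the conditional split distribution fine-grained enough that the
discrete exact p-values approximate uniformity (atoms at p = 1 stay
below a few percent). The recovery check plants 200 four-fold features
among 2,000 under the same design. The host-correlation fixture plants
50 coupled (σ = 0.15 multiplicative noise) and 50 independent pairs
over 10 samples. The end-to-end problem sizes (~60 circles, ~25,000
reads per cohort) keep a full pipeline run around half a minute on one
core.

## Numerical details

* The exact-test p snaps to 1.0 when the observed split is modal
  (avoids 1 − ε from floating-point summation).
* Dispersion floor 10⁻⁶; zero-variance features give the floor.
* BH uses a stable mergesort so ties are deterministic.
* The manifest hash is a SHA-256 over parameters and per-stage counts;
  reruns with the same seed and config are bit-identical.

## Known limitations

* The toy aligner is exact-substring (plus a mismatch knob for genomic
  matches); transcript matching is always exact, so `mm > 0` improves
  genomic recovery only.
* `mm > 0` anchor placement falls back to a vectorized scan that is
  ~1000× slower than the hash index; it is an ablation path, not the
  default.
* Venn-region counting is exact-key; the `--slack` option does fuzzy
  membership per key but reports regions over observed keys, which can
  over-count when slack merges distinct junctions.
* The two-gene exon-composition convention (read-through splicing) is
  one of several defensible readings of a junction spanning two genes;
  it is applied consistently in the generator and annotator.
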