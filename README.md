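# circheart

Desk-scale circular RNA (circRNA) analysis for heart RNA-seq, built around
a synthetic-data generator with complete ground truth.

## The problem

circRNAs are covalently closed transcripts formed by *back-splicing*: a
downstream splice donor joins an upstream splice acceptor, so the junction
reads non-colinearly (acceptor coordinate < donor coordinate on the
genome). In bulk rRNA-depleted RNA-seq of human left ventricle —
e.g. dilated cardiomyopathy (DCM) vs normal hearts, five samples per
group — circRNAs are detected from reads that fail to align contiguously
but whose two ends map in *reversed orientation*. Several published
"read-through" circRNAs joining exons of two adjacent genes are in fact
artifacts of read misalignment between highly homologous neighbors (the
MYH6/MYH7 case); separating true read-through (rt-)circRNAs from these
artifacts is a sequence-homology decision, not an alignment one.

`circheart` re-implements this analysis chain as a tested, reusable
library + CLI:

1. **Junction calling** (`circheart.caller`) — terminal 20-mer anchors
   placed uniquely on the genome; reversed-orientation anchor pairs are
   extended to a breakpoint flanked by the canonical `AG | ... | GT`
   splice signal on the transcribed strand. Detection rule: ≥ 2 unique
   back-spliced reads in ≥ 1 sample.
2. **Origin annotation** (`circheart.annotate`) — CDS / UTR-CDS / UTR /
   intronic / intergenic / two-gene classes, exon composition, circular
   spliced sequence, naming (`circGENE_n`, `GENE1_e4:GENE2_e2`).
3. **rt vs homology artifact** (`circheart.rt`) — the 50-bp flanks on each
   side of the back-splice are aligned (Smith–Waterman, match +1,
   mismatch −2, gap open −5, extend −2) against the cDNA of both candidate
   host genes; a flank hitting *both* genes (identity ≥ 0.8 over ≥ 25 nt)
   marks the circRNA as a likely artifact, otherwise it is a true
   rt-circRNA.
4. **Quantification** (`circheart.quantify`) — SRPBM
   (`count · 10⁹ / total mapped reads`), FPKM
   (`count · 10⁹ / (exon length · total fragments)`), the high-confidence
   tier (≥ 2 reads in ≥ 4 samples of one group), sample-presence profiles,
   and Pearson circRNA–host-gene correlation vs random gene pairs
   (Wilcoxon rank-sum comparison).
5. **Differential expression** (`circheart.differential`) — conditional
   negative-binomial exact test with a common method-of-moments
   dispersion φ (variance = μ + φμ²); conditional on the total
   *t = sum_A + sum_B*, the two-sided p is the probability mass of all
   splits no more likely than the observed one (φ→0 reduces to a binomial
   split). circRNAs: significant at raw p < 0.05 and FC > 2; linear genes:
   BH-FDR < 0.05 and FC > 2.
6. **miRNA sponge screen** (`circheart.sponge`) — canonical seed-site
   counting (8mer / 7mer-m8 / 7mer-A1, optional 6mer) on the *circular*
   sequence including junction-wrapping sites; candidates have ≥ 5 sites
   for some miRNA, the top tier ≥ 10; circRNA–miRNA–mRNA edge lists are
   Cytoscape-importable.
7. **Cross-study overlap** (`circheart.compare`) — exact canonical-key
   venn-region counts for 2–5 junction sets on one assembly.

The synthetic generator (`circheart.simulate`) builds a toy genome whose
gene layout reproduces the two critical configurations — an adjacent
same-strand ~95%-identity homolog pair (misalignment trap) and an
adjacent same-strand independent pair (rt source) — plants ~60 circRNAs
of every origin class with per-sample support and 4-fold group effects,
writes single-end FASTQ reads, injects miRNA seed sites, and emits truth
tables for every stage.

## Worked example

One command generates the default fixture (seed 1), runs the whole
pipeline and scores it against the planted truth:

```sh
$ circheart demo --seed 1
{
  "n_truth_detectable": 60,
  "n_detected": 60,
  "junction_recall": 1.0,
  "junction_precision": 1.0,
  "origin_accuracy": 1.0,
  "rt_accuracy": 1.0,
  "rt_n": 20,
  "de_sensitivity": 1.0,
  "de_false_positive_rate": 0.041666666666666664,
  "sponge_candidates_recovered": true,
  "host_corr_ranksum_p": 0.04947579390817799,
  "manifest_hash": "31b351b0e70ccd0e"
}
```

Reading this: all 60 planted junctions (every one carried ≥ 2 unique
back-spliced reads somewhere) were recovered with no false calls;
origin classes all match the planted truth; the 10 planted rt-circRNAs
and 10 homology-artifact configurations were all classified correctly
(`rt_accuracy` 1.0 over `rt_n` = 20); every planted 4-fold circRNA was
recovered by the exact test at p < 0.05 & FC > 2, with a 4.2% false-call
rate among planted nulls; the planted 12-site and 5-site sponge
circRNAs reached their tiers. The run is bit-reproducible per seed
(`manifest_hash`).

Stage-by-stage over files:

```sh
circheart simulate --seed 1 --out fx/
circheart run --genome fx/genome.fa --gtf fx/annotation.gtf \
    --samples fx/samples.tsv --mirnas fx/mirnas.tsv --targets fx/targets.tsv \
    $(for f in fx/*.fastq; do echo --reads $f; done) --out out/
```

`out/` then holds `junctions.bed` + per-sample support, annotated records
and circular sequences (FASTA), rt calls with alignment evidence, count
matrices, SRPBM/FPKM tables, DE tables, the miRNA site table, sponge
candidates and the network edge list, plus a `manifest.json` recording
parameters and per-stage counts. Individual subcommands (`callcirc`,
`annotate`, `rtclass`, `quantify`, `de`, `sponge`, `compare`) run single
stages.

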