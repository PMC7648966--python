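"""End-to-end orchestration: detection -> annotation -> rt screen ->
quantification -> differential -> sponge screen, plus truth-table
evaluation and the one-command demo.

The pipeline operates on in-memory objects (`run_stages`) or on files
(`run_pipeline`); the demo generates the default synthetic fixture, runs
everything, and reports recall/precision, rt-classification accuracy,
differential-expression recovery and sponge-candidate recovery against
the planted truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import caller, differential, quantify, rt, sponge
from .io import (read_fasta, read_fastq, read_gtf, read_sample_sheet,
                 write_count_matrix, write_fasta, write_junction_bed)
from .models import CountMatrix, GenomeBundle
from .simulate import Fixture, SimConfig, make_fixture


@dataclass
class PipelineParams:
    """Stage parameters with the pipeline's documented defaults."""

    k: int = 20
    mm: int = 0
    min_reads: int = 2
    min_samples: int = 4
    flank: int = 50
    min_identity: float = 0.8
    min_length: int = 25
    fc: float = 2.0
    alpha: float = 0.05
    min_sites: int = 5
    top_sites: int = 10
    include_6mer: bool = False
    n_random_pairs: int = 50
    seed: int = 0


@dataclass
class PipelineResult:
    junctions: list = field(default_factory=list)
    mapped_totals: dict = field(default_factory=dict)
    caller_stats: dict = field(default_factory=dict)
    records: list = field(default_factory=list)
    rt_table: pd.DataFrame | None = None
    circ_matrix: CountMatrix | None = None
    srpbm: pd.DataFrame | None = None
    high_confidence: list = field(default_factory=list)
    presence: pd.Series | None = None
    gene_matrix: CountMatrix | None = None
    fpkm: pd.DataFrame | None = None
    host_corr: dict | None = None
    circ_de: pd.DataFrame | None = None
    gene_de: pd.DataFrame | None = None
    site_table: pd.DataFrame | None = None
    candidates: pd.DataFrame | None = None
    top_tier: pd.DataFrame | None = None
    edges: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def count_genes(reads_by_sample: dict[str, list[tuple[str, str]]],
                genome: GenomeBundle) -> dict[str, dict[str, int]]:
    """Toy linear gene counting: a read counts for a gene iff it is an
    exact substring of the gene's spliced transcript sequence."""
    transcripts = [(g.gene_id, g.spliced_sequence(genome.sequences))
                   for g in genome.genes]
    out: dict[str, dict[str, int]] = {}
    for sample, reads in reads_by_sample.items():
        counts = {gid: 0 for gid, _ in transcripts}
        for _rid, seq in reads:
            for gid, tseq in transcripts:
                if seq in tseq:
                    counts[gid] += 1
                    break
        out[sample] = counts
    return out


def run_stages(genome: GenomeBundle,
               reads_by_sample: dict[str, list[tuple[str, str]]],
               groups: dict[str, str],
               mirnas: pd.DataFrame | None = None,
               mirna_targets: pd.DataFrame | None = None,
               params: PipelineParams | None = None) -> PipelineResult:
    """Run every stage on in-memory inputs."""
    p = params or PipelineParams()
    res = PipelineResult()
    samples = list(reads_by_sample)

    # detection
    res.junctions, res.mapped_totals, res.caller_stats = \
        caller.call_sample_junctions(reads_by_sample, genome, k=p.k,
                                     mm=p.mm, min_reads=p.min_reads)
    # annotation
    res.records = ann.annotate_junctions(res.junctions, genome)
    # rt screen
    res.rt_table = rt.screen_all(res.records, genome, flank=p.flank,
                                 min_identity=p.min_identity,
                                 min_length=p.min_length)
    # quantification
    totals = np.array([res.mapped_totals[s] for s in samples], dtype=float)
    counts = np.array([[r.junction.support.get(s, 0) for s in samples]
                       for r in res.records], dtype=np.int64)
    res.circ_matrix = CountMatrix([r.name for r in res.records], samples,
                                  counts, totals, dict(groups))
    res.srpbm = quantify.srpbm_table(res.circ_matrix)
    res.high_confidence = quantify.tier_filter(
        res.circ_matrix, min_reads=p.min_reads, min_samples=p.min_samples)
    res.presence = quantify.presence_profile(res.circ_matrix,
                                             min_reads=p.min_reads)
    gene_counts = count_genes(reads_by_sample, genome)
    gmat = np.array([[gene_counts[s][g.gene_id] for s in samples]
                     for g in genome.genes], dtype=np.int64)
    res.gene_matrix = CountMatrix([g.gene_id for g in genome.genes],
                                  samples, gmat, totals, dict(groups))
    res.fpkm = quantify.fpkm_table(res.gene_matrix, genome.genes)
    pairs = {r.name: r.host_genes[0] for r in res.records
             if len(r.host_genes) == 1}
    try:
        res.host_corr = quantify.host_correlation(
            res.srpbm, res.fpkm, pairs,
            n_random=p.n_random_pairs, seed=p.seed)
    except ValueError:
        res.host_corr = None
    # differential
    hc = res.circ_matrix.subset(res.high_confidence) \
        if res.high_confidence else res.circ_matrix
    res.circ_de = differential.de_table(hc, fc_threshold=p.fc,
                                        alpha=p.alpha,
                                        significance="pvalue")
    res.gene_de = differential.de_table(res.gene_matrix, fc_threshold=p.fc,
                                        alpha=p.alpha, significance="fdr")
    # sponge screen
    if mirnas is not None and len(mirnas):
        panel = [sponge.MiRNA(r.id, r.sequence)
                 for r in mirnas.itertuples()]
        hc_set = set(res.high_confidence)
        seqs = {r.name: r.spliced_seq for r in res.records
                if r.name in hc_set and r.spliced_seq}
        res.site_table = sponge.site_count_table(seqs, panel,
                                                 include_6mer=p.include_6mer)
        _, res.candidates, res.top_tier = sponge.sponge_candidates(
            res.site_table, min_sites=p.min_sites, top_sites=p.top_sites)
        targets = mirna_targets if mirna_targets is not None \
            else pd.DataFrame(columns=["mirna", "gene"])
        _, res.edges = sponge.build_network(res.site_table, res.candidates,
                                            targets, res.gene_de,
                                            min_sites=p.min_sites)
    res.manifest = _manifest(res, p)
    return res


def _manifest(res: PipelineResult, p: PipelineParams) -> dict:
    man = {
        "params": {k: v for k, v in vars(p).items()},
        "stage_counts": {
            "junctions_detected": len(res.junctions),
            "records_annotated": len(res.records),
            "two_gene": int(sum(r.origin == "two-gene"
                                for r in res.records)),
            "true_rt": int((res.rt_table["call"] == "true_rt").sum())
            if res.rt_table is not None and len(res.rt_table) else 0,
            "homology_artifact":
                int((res.rt_table["call"] == "homology_artifact").sum())
                if res.rt_table is not None and len(res.rt_table) else 0,
            "high_confidence": len(res.high_confidence),
            "circ_de_significant":
                int((res.circ_de["direction"] != "ns").sum())
                if res.circ_de is not None else 0,
            "gene_de_significant":
                int((res.gene_de["direction"] != "ns").sum())
                if res.gene_de is not None else 0,
            "sponge_candidates": len(res.candidates)
            if res.candidates is not None else 0,
        },
    }
    blob = json.dumps(man, sort_keys=True, default=str).encode()
    man["hash"] = hashlib.sha256(blob).hexdigest()[:16]
    return man


# ------------------------------------------------------------------ files

def run_pipeline(genome_fa, gtf, fastqs: dict[str, str], sample_sheet,
                 outdir, mirna_tsv=None, targets_tsv=None,
                 params: PipelineParams | None = None) -> PipelineResult:
    """File-based entry point; writes all stage artifacts under outdir."""
    for path in [genome_fa, gtf, sample_sheet] + list(fastqs.values()):
        if not Path(path).exists():
            raise FileNotFoundError(path)
    genome = GenomeBundle(read_fasta(genome_fa), read_gtf(gtf))
    genome.validate()
    groups = read_sample_sheet(sample_sheet)
    reads = {s: read_fastq(f) for s, f in fastqs.items()}
    mirnas = pd.read_csv(mirna_tsv, sep="\t") if mirna_tsv else None
    targets = pd.read_csv(targets_tsv, sep="\t") if targets_tsv else None
    res = run_stages(genome, reads, groups, mirnas, targets, params)
    write_outputs(res, outdir)
    return res


def write_outputs(res: PipelineResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_junction_bed(res.junctions, outdir / "junctions.bed",
                       outdir / "junction_support.tsv")
    recs = pd.DataFrame([{
        "name": r.name, "chrom": r.junction.chrom,
        "start": r.junction.start, "end": r.junction.end,
        "strand": r.junction.strand, "origin": r.origin,
        "host_genes": ",".join(r.host_genes),
        "exon_composition": ";".join(f"{g}:{i}"
                                     for g, i in r.exon_composition),
        "spliced_length": r.spliced_length,
        "high_confidence": r.name in set(res.high_confidence)}
        for r in res.records])
    recs.to_csv(outdir / "circ_records.tsv", sep="\t", index=False)
    write_fasta({r.name: r.spliced_seq for r in res.records if r.spliced_seq},
                outdir / "circ_sequences.fa")
    if res.rt_table is not None:
        res.rt_table.to_csv(outdir / "rt_calls.tsv", sep="\t", index=False)
    if res.circ_matrix is not None:
        write_count_matrix(res.circ_matrix, outdir / "circ_counts.tsv")
        res.srpbm.to_csv(outdir / "circ_srpbm.tsv", sep="\t")
        res.presence.to_csv(outdir / "presence_profile.tsv", sep="\t")
    if res.gene_matrix is not None:
        write_count_matrix(res.gene_matrix, outdir / "gene_counts.tsv")
        res.fpkm.to_csv(outdir / "gene_fpkm.tsv", sep="\t")
    if res.host_corr is not None:
        res.host_corr["table"].to_csv(outdir / "host_correlation.tsv",
                                      sep="\t", index=False)
    if res.circ_de is not None:
        res.circ_de.to_csv(outdir / "circ_de.tsv", sep="\t", index=False)
    if res.gene_de is not None:
        res.gene_de.to_csv(outdir / "gene_de.tsv", sep="\t", index=False)
    if res.site_table is not None:
        res.site_table.to_csv(outdir / "mirna_sites.tsv", sep="\t",
                              index=False)
        res.candidates.to_csv(outdir / "sponge_candidates.tsv", sep="\t",
                              index=False)
        res.edges.to_csv(outdir / "network_edges.tsv", sep="\t",
                         index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(res.manifest, indent=2, default=str) + "\n")


# ------------------------------------------------------------------ truth

def evaluate_against_truth(res: PipelineResult, fix: Fixture) -> dict:
    """Score pipeline output against the planted truth tables."""
    truth = fix.truth
    min_reads = 2
    sup_cols = [c for c in truth.circs.columns if c.startswith("support_")]
    detectable = truth.circs[
        (truth.circs[sup_cols] >= min_reads).any(axis=1)]
    truth_keys = {(r.chrom, int(r.start), int(r.end), r.strand): r.truth_name
                  for r in detectable.itertuples()}
    found_keys = {j.key for j in res.junctions}
    tp = len(set(truth_keys) & found_keys)
    recall = tp / len(truth_keys) if truth_keys else float("nan")
    precision = tp / len(found_keys) if found_keys else float("nan")

    # origin-class accuracy on planted (boundary-exact planting)
    key2rec = {r.junction.key: r for r in res.records}
    origin_ok = origin_n = 0
    for key, tname in truth_keys.items():
        if key in key2rec:
            torigin = truth.circs.set_index("truth_name").loc[tname, "origin"]
            origin_n += 1
            origin_ok += int(key2rec[key].origin == torigin)

    # rt classification accuracy
    rt_ok = rt_n = 0
    if res.rt_table is not None and len(res.rt_table):
        name2key = {r.name: r.junction.key for r in res.records}
        t = truth.circs.set_index("truth_name")
        key2status = {(r.chrom, int(r.start), int(r.end), r.strand):
                      r.rt_status for r in truth.circs.itertuples()}
        for row in res.rt_table.itertuples():
            key = name2key.get(row.name)
            status = key2status.get(key)
            if status in ("true_rt", "homology_artifact"):
                rt_n += 1
                rt_ok += int(row.call == status)

    # DE recovery among high-confidence circles
    de_sens = de_fpr = float("nan")
    if res.circ_de is not None:
        name2key = {r.name: r.junction.key for r in res.records}
        key2fc = {(r.chrom, int(r.start), int(r.end), r.strand):
                  r.fold_change for r in truth.circs.itertuples()}
        planted = nulls = hits = fp = 0
        for row in res.circ_de.itertuples():
            key = name2key.get(row.feature_id)
            fc = key2fc.get(key)
            if fc is None:
                continue
            want = "up" if fc > 1 else ("down" if fc < 1 else "ns")
            if want != "ns":
                planted += 1
                hits += int(row.direction == want)
            else:
                nulls += 1
                fp += int(row.direction != "ns")
        de_sens = hits / planted if planted else float("nan")
        de_fpr = fp / nulls if nulls else float("nan")

    # sponge recovery: planted >= 5-site circs should be candidates
    sponge_ok = True
    if res.candidates is not None and len(truth.mirna_sites):
        key2name = {r.junction.key: r.name for r in res.records}
        t = truth.circs.set_index("truth_name")
        cand_set = set(res.candidates["circ"])
        planted_tot = truth.mirna_sites.groupby("circ")["count"].sum()
        for tname, total in planted_tot.items():
            row = t.loc[tname]
            key = (row.chrom, int(row.start), int(row.end), row.strand)
            name = key2name.get(key)
            if total >= 5 and name is not None:
                sponge_ok &= name in cand_set

    return {
        "n_truth_detectable": len(truth_keys),
        "n_detected": len(found_keys),
        "junction_recall": recall,
        "junction_precision": precision,
        "origin_accuracy": origin_ok / origin_n if origin_n else float("nan"),
        "rt_accuracy": rt_ok / rt_n if rt_n else float("nan"),
        "rt_n": rt_n,
        "de_sensitivity": de_sens,
        "de_false_positive_rate": de_fpr,
        "sponge_candidates_recovered": bool(sponge_ok),
        "host_corr_ranksum_p": (res.host_corr or {}).get("ranksum_p",
                                                         float("nan")),
    }


def demo(seed: int = 1, outdir=None,
         config: SimConfig | None = None) -> dict:
    """Generate the default fixture, run the pipeline, report the summary."""
    cfg = config or SimConfig(seed=seed)
    fix = make_fixture(cfg)
    params = PipelineParams(seed=seed)
    res = run_stages(fix.genome, fix.reads, fix.config.groups,
                     fix.truth.mirnas, fix.truth.mirna_targets, params)
    summary = evaluate_against_truth(res, fix)
    summary["manifest_hash"] = res.manifest["hash"]
    if outdir is not None:
        write_outputs(res, outdir)
        (Path(outdir) / "demo_summary.json").write_text(
            json.dumps(summary, indent=2, default=str) + "\n")
    return summary
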