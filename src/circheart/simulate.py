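"""Synthetic heart RNA-seq fixture with complete truth tables.

Generates a toy multi-gene genome and annotation emulating the statistical
structure of a 5-vs-5 ribo-depleted heart RNA-seq study:

* a pair of adjacent, same-strand, highly homologous genes (the
  misalignment trap, an MYH6/MYH7-like configuration),
* a pair of adjacent, same-strand, independently drawn genes (the
  read-through source, a SCAF8/TIAM2-like configuration),
* planted circRNAs of every genomic-origin class (CDS, UTR, UTR-CDS,
  intronic, intergenic, two-gene) with per-sample back-splice read support
  and planted group fold changes,
* single-end FASTQ reads per sample, including back-splice-spanning reads,
* a toy miRNA panel with seed-match sites injected into selected circRNA
  sequences (written back into the genome so every downstream stage sees
  them),
* truth tables for every stage.

Everything is deterministic under a fixed seed (byte-identical files).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import write_fasta, write_fastq, write_gtf, write_sample_sheet
from .models import GeneModel, GenomeBundle, revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Raised when a SimConfig cannot be realized."""


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic fixture.

    Defaults encode the emulated study conditions: two groups of five
    samples, 100-nt single-end error-free reads, a 95%-identity homolog
    trap, ~60 planted circRNAs with per-sample back-splice support of at
    least 3 reads, and 4-fold planted group effects.
    """

    seed: int = 1
    n_genes: int = 14              # includes the trap pair and the rt pair
    chrom_length: int = 240_000
    read_length: int = 100
    n_samples_per_group: int = 5
    error_rate: float = 0.0
    homolog_identity: float = 0.95
    group_names: tuple[str, str] = ("normal", "DCM")
    # gene architecture
    exons_per_gene: tuple[int, int] = (8, 12)
    exon_length: tuple[int, int] = (130, 300)
    intron_length: tuple[int, int] = (150, 400)
    intergenic_gap: tuple[int, int] = (300, 600)
    # planted circRNAs per origin class
    n_cds_circ: int = 24
    n_utr_circ: int = 3
    n_utrcds_circ: int = 3
    n_intronic_circ: int = 5
    n_intergenic_circ: int = 5
    n_rt_circ: int = 10            # true read-through, on the rt pair
    n_artifact_circ: int = 10      # homology artifacts, on the trap pair
    # read-level abundances
    support_range: tuple[int, int] = (3, 8)    # per-sample back-splice reads
    circ_fold_change: float = 4.0
    n_circ_up: int = 6
    n_circ_down: int = 6
    background_reads_per_circ: int = 2
    min_overhang: int = 20         # junction overlap of spanning reads
    # linear genes
    gene_count_range: tuple[int, int] = (80, 200)  # reads/gene/sample
    gene_fold_change: float = 4.0
    n_gene_up: int = 2
    n_gene_down: int = 2
    sample_cv: float = 0.35        # lognormal sigma of per-sample factors
    n_coupled_circ: int = 8        # circs sharing their host's sample factor
    # miRNA panel
    n_mirnas: int = 10
    mirna_length: int = 22

    @property
    def n_samples(self) -> int:
        return 2 * self.n_samples_per_group

    @property
    def sample_ids(self) -> list[str]:
        a, b = self.group_names
        n = self.n_samples_per_group
        return [f"{a}_{i + 1}" for i in range(n)] + \
               [f"{b}_{i + 1}" for i in range(n)]

    @property
    def groups(self) -> dict[str, str]:
        a, b = self.group_names
        n = self.n_samples_per_group
        return {s: (a if i < n else b)
                for i, s in enumerate(self.sample_ids)}


@dataclass
class TruthTable:
    """Ground truth for every pipeline stage.

    ``circs`` has one row per planted circRNA: junction key, origin class,
    host gene(s), rt status, exon composition, spliced sequence, planted
    fold change and one ``support_<sample>`` column per sample.
    """

    circs: pd.DataFrame
    gene_counts: pd.DataFrame          # genes x samples linear read counts
    mirna_sites: pd.DataFrame          # circ, mirna, site_type, count
    mirnas: pd.DataFrame               # id, sequence (RNA 5'->3')
    mirna_targets: pd.DataFrame        # mirna, gene
    read_totals: dict[str, int] = field(default_factory=dict)

    def junction_keys(self) -> set[tuple]:
        return {(r.chrom, int(r.start), int(r.end), r.strand)
                for r in self.circs.itertuples()}


# ------------------------------------------------------------------ genome

def _rand_seq(rng, n) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def _plant(arr: np.ndarray, pos: int, s: str) -> None:
    arr[pos:pos + len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)


def _splice_signals(arr, exons, strand) -> None:
    """Force canonical GT/AG (gene strand) at every intron boundary."""
    ivs = sorted(exons)
    for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
        if strand == "+":
            _plant(arr, b1, "GT")       # donor at intron start
            _plant(arr, a2 - 2, "AG")   # acceptor at intron end
        else:
            _plant(arr, b1, "CT")       # genomic CT = AG on minus strand
            _plant(arr, a2 - 2, "AC")   # genomic AC = GT on minus strand


def _mutate_copy(rng, arr: np.ndarray, rate: float, guard: int = 19) -> np.ndarray:
    """Substitute ~rate of positions; no run of >= guard identical bases.

    The run guard keeps every identical run below ``guard``, so every
    20-mer of the copy differs from the original and exact anchor
    placement stays unambiguous between the two homologs.  Because the
    guard itself substitutes at rate ~1/guard in otherwise-identical
    stretches, the i.i.d. rate is solved (bisection) so the *combined*
    substitution rate matches ``rate``; measured identity lands within a
    few percent of ``1 - rate``.
    """
    def combined(r):
        # mean gap between substitutions = E[min(Geom(r), guard)]
        if r <= 0:
            return 1.0 / guard
        return r / (1.0 - (1.0 - r) ** guard)

    if rate <= 1.0 / guard:
        r_iid = 0.0
    else:
        lo, hi = 0.0, rate * 2
        while combined(hi) < rate:
            hi *= 2
        for _ in range(60):
            mid = (lo + hi) / 2
            lo, hi = (mid, hi) if combined(mid) < rate else (lo, mid)
        r_iid = lo

    out = arr.copy()

    def sub(i):
        choices = BASES[BASES != arr[i]]
        out[i] = choices[rng.integers(0, len(choices))]

    hits = rng.random(len(arr)) < r_iid
    run = 0
    for i in range(len(arr)):
        if hits[i]:
            sub(i)
        if out[i] == arr[i]:
            run += 1
            if run >= guard:
                sub(i)      # break the run at length guard-1
                run = 0
        else:
            run = 0
    return out


def generate_genome(config: SimConfig) -> GenomeBundle:
    """Build the toy chromosome and gene models.

    Layout: regular genes, then the homolog trap pair (same-strand
    adjacent, the second a mutated copy of the first), then the
    read-through pair (same-strand adjacent, independent sequences).
    Every intron carries canonical GT/AG signals on the gene strand.
    """
    rng = np.random.default_rng(config.seed)
    L = config.chrom_length
    arr = _rand_seq(rng, L)
    genes: list[GeneModel] = []
    n_regular = config.n_genes - 4
    if n_regular < 1:
        raise ConfigError("n_genes must be >= 5")

    cursor = int(rng.integers(*config.intergenic_gap))

    def make_structure():
        n_ex = int(rng.integers(*config.exons_per_gene))
        exs = rng.integers(*config.exon_length, size=n_ex)
        ins = rng.integers(*config.intron_length, size=n_ex - 1)
        return exs, ins

    def place(gene_id, strand, exs, ins, region=None):
        nonlocal cursor
        start = cursor
        exons = []
        p = start
        for i, el in enumerate(exs):
            exons.append((p, p + int(el)))
            p += int(el)
            if i < len(ins):
                p += int(ins[i])
        if p > L:
            raise ConfigError(
                f"chrom_length {L} too small to place gene {gene_id}")
        if region is not None:
            arr[start:p] = region[: p - start]
        _splice_signals(arr, exons, strand)
        # CDS: from mid of the 3rd exon to mid of the 3rd-from-last exon
        # (genomic order); exons fully inside are pure CDS, outside pure UTR.
        ivs = sorted(exons)
        cds = []
        if len(ivs) >= 6:
            c0 = ivs[2][0] + (ivs[2][1] - ivs[2][0]) // 2
            c1 = ivs[-3][0] + (ivs[-3][1] - ivs[-3][0]) // 2
            for a, b in ivs:
                lo, hi = max(a, c0), min(b, c1)
                if lo < hi:
                    cds.append((lo, hi))
        order = ivs if strand == "+" else ivs[::-1]
        g = GeneModel(gene_id, "chrS", strand, tuple(order), tuple(cds),
                      "coding" if cds else "noncoding")
        genes.append(g)
        cursor = p + int(rng.integers(*config.intergenic_gap))
        return g

    for i in range(n_regular):
        strand = "+" if rng.random() < 0.7 else "-"
        exs, ins = make_structure()
        place(f"GENE{i + 1:02d}", strand, exs, ins)

    # homolog trap pair: HOMB is a mutated copy of HOMA's genomic span
    exs, ins = make_structure()
    homa = place("HOMA", "+", exs, ins)
    copy = _mutate_copy(rng, arr[homa.start:homa.end],
                        1.0 - config.homolog_identity)
    place("HOMB", "+", exs, ins, region=copy)

    # read-through pair: independent sequences, adjacent, same strand
    exs, ins = make_structure()
    place("RTUP", "+", exs, ins)
    exs, ins = make_structure()
    place("RTDN", "+", exs, ins)

    bundle = GenomeBundle({"chrS": arr.tobytes().decode()}, genes)
    bundle.validate()
    return bundle


# ------------------------------------------------------------------ circRNAs

def _splice_map(genome: GenomeBundle, exon_ivs: list[tuple[int, int]],
                strand: str) -> tuple[str, list[int]]:
    """Spliced sequence plus per-base genomic positions (for write-back).

    ``exon_ivs`` are genomic-sorted intervals; for '-' the sequence is the
    reverse complement read in transcription order and the map lists the
    genomic position whose *complement* each spliced base is.
    """
    chrom = genome.sequences["chrS"]
    seq, gmap = [], []
    order = exon_ivs if strand == "+" else exon_ivs[::-1]
    for a, b in order:
        if strand == "+":
            seq.append(chrom[a:b])
            gmap.extend(range(a, b))
        else:
            seq.append(revcomp(chrom[a:b]))
            gmap.extend(range(b - 1, a - 1, -1))
    return "".join(seq), gmap


def _seq_from_map(chrom: str, gmap: list[int], strand: str) -> str:
    if strand == "+":
        return "".join(chrom[p] for p in gmap)
    return "".join(revcomp(chrom[p]) for p in gmap)


def _circle_exons(gene: GeneModel, i: int, j: int) -> list[tuple[int, int]]:
    """Genomic intervals of transcription-order exons i..j (1-based, incl.)."""
    return sorted(gene.exons[t] for t in range(i - 1, j))


def plant_circrnas(genome: GenomeBundle, config: SimConfig) -> TruthTable:
    """Plant circRNAs of every origin class and fill per-sample support.

    Two-gene circles on the rt pair are true read-throughs; two-gene
    circles on the trap pair model the homology artifact (junctions an
    aligner tolerant of mismatches would produce by misassigning reads
    across the homologs).  Intronic and intergenic circles get GT/AG
    signals written at their junctions so the splice-signal rule can see
    them.
    """
    rng = np.random.default_rng(config.seed + 1)
    chrom_arr = np.frombuffer(genome.sequences["chrS"].encode(),
                              dtype=np.uint8).copy()
    rows = []

    def add(origin, hosts, exon_comp, start, end, strand, rt_status, seq, gmap):
        rows.append(dict(chrom="chrS", start=int(start), end=int(end),
                         strand=strand, origin=origin,
                         host_genes=",".join(hosts),
                         exon_composition=";".join(
                             f"{g}:{i}" for g, i in exon_comp),
                         rt_status=rt_status, spliced_seq=seq,
                         spliced_length=len(seq), gmap=gmap))

    regular = [g for g in genome.genes if g.gene_id.startswith("GENE")]
    used: set[tuple] = set()

    def shuffled(items):
        idx = rng.permutation(len(items))
        return [items[k] for k in idx]

    def pick_span(gene, lo, hi, n):
        combos = [(i, j) for i in range(lo, hi + 1) for j in range(i, hi + 1)
                  if (gene.gene_id, i, j) not in used]
        return shuffled(combos)[:n]

    def exon_class(gene, i, j):
        """Origin class of a circle over exons i..j by CDS coverage."""
        cds_cov = tot = 0
        for a, b in _circle_exons(gene, i, j):
            tot += b - a
            for ca, cb in gene.cds_ranges:
                cds_cov += max(0, min(b, cb) - max(a, ca))
        if cds_cov == 0:
            return "UTR"
        return "CDS" if cds_cov == tot else "UTR-CDS"

    def plant_single(gene, i, j):
        ivs = _circle_exons(gene, i, j)
        start, end = ivs[0][0], ivs[-1][1]
        seq, gmap = _splice_map(genome, ivs, gene.strand)
        comp = [(gene.gene_id, t) for t in range(i, j + 1)]
        add(exon_class(gene, i, j), [gene.gene_id], comp, start, end,
            gene.strand, "n/a", seq, gmap)
        used.add((gene.gene_id, i, j))

    # CDS circles: transcription-order exons 4 .. n-3 are pure CDS by
    # construction on either strand
    n_left, gi = config.n_cds_circ, 0
    while n_left > 0:
        if gi > 10 * len(regular):
            raise ConfigError("cannot place requested CDS circles")
        gene = regular[gi % len(regular)]
        gi += 1
        lo, hi = 4, gene.n_exons - 3
        if hi < lo:
            continue
        for (i, j) in pick_span(gene, lo, hi, min(3, n_left)):
            plant_single(gene, i, j)
            n_left -= 1

    # UTR circles: exon 2 alone (pure UTR on either strand by construction)
    for gene in regular[:config.n_utr_circ]:
        if (gene.gene_id, 2, 2) not in used:
            plant_single(gene, 2, 2)

    # UTR-CDS circles: exons 2..4 cross the CDS boundary
    for gene in regular[-config.n_utrcds_circ:]:
        if (gene.gene_id, 2, 4) not in used:
            plant_single(gene, 2, 4)

    # intronic circles: inside an intron, signals planted at the junction
    picked, gi = 0, 0
    while picked < config.n_intronic_circ and gi < 6 * len(regular):
        gene = regular[gi % len(regular)]
        gi += 1
        ivs = sorted(gene.exons)
        k = int(rng.integers(0, len(ivs) - 1))
        ia, ib = ivs[k][1], ivs[k + 1][0]
        span = int(rng.integers(config.read_length + 20,
                                config.read_length + 80))
        if ib - ia < span + 30:
            continue
        start = ia + 5 + int(rng.integers(0, ib - ia - span - 20))
        end = start + span
        if gene.strand == "+":
            _plant(chrom_arr, start - 2, "AG")
            _plant(chrom_arr, end, "GT")
        else:
            _plant(chrom_arr, start - 2, "AC")
            _plant(chrom_arr, end, "CT")
        gmap = (list(range(start, end)) if gene.strand == "+"
                else list(range(end - 1, start - 1, -1)))
        seq = _seq_from_map(chrom_arr.tobytes().decode(), gmap, gene.strand)
        add("intronic", [gene.gene_id], [], start, end, gene.strand,
            "n/a", seq, gmap)
        picked += 1
    if picked < config.n_intronic_circ:
        raise ConfigError("cannot place requested intronic circles")

    # intergenic circles: in gaps between genes, + strand, signals planted
    bounds = sorted((g.start, g.end) for g in genome.genes)
    gaps = [(b1, a2) for (_, b1), (a2, _) in zip(bounds, bounds[1:])
            if a2 - b1 > config.read_length + 160]
    if len(gaps) < config.n_intergenic_circ:
        raise ConfigError("not enough intergenic gaps")
    for k in range(config.n_intergenic_circ):
        ga, gb = gaps[k]
        span = int(rng.integers(config.read_length + 20,
                                config.read_length + 80))
        start = ga + 20 + int(rng.integers(0, gb - ga - span - 42))
        end = start + span
        _plant(chrom_arr, start - 2, "AG")
        _plant(chrom_arr, end, "GT")
        gmap = list(range(start, end))
        seq = chrom_arr[start:end].tobytes().decode()
        add("intergenic", [], [], start, end, "+", "n/a", seq, gmap)

    # two-gene circles: exons i..n of the upstream gene + 1..j downstream
    def plant_two_gene(up: GeneModel, dn: GeneModel, i: int, j: int, status):
        ivs = _circle_exons(up, i, up.n_exons) + _circle_exons(dn, 1, j)
        start, end = up.exons[i - 1][0], dn.exons[j - 1][1]
        seq, gmap = _splice_map(genome, ivs, "+")
        comp = ([(up.gene_id, t) for t in range(i, up.n_exons + 1)] +
                [(dn.gene_id, t) for t in range(1, j + 1)])
        add("two-gene", [up.gene_id, dn.gene_id], comp, start, end, "+",
            status, seq, gmap)

    def two_gene_combos(up, dn, n):
        combos = [(i, j) for i in range(2, up.n_exons)
                  for j in range(1, dn.n_exons)]
        return shuffled(combos)[:n]

    rtu, rtd = genome.gene("RTUP"), genome.gene("RTDN")
    hma, hmb = genome.gene("HOMA"), genome.gene("HOMB")
    for (i, j) in two_gene_combos(rtu, rtd, config.n_rt_circ):
        plant_two_gene(rtu, rtd, i, j, "true_rt")
    for (i, j) in two_gene_combos(hma, hmb, config.n_artifact_circ):
        plant_two_gene(hma, hmb, i, j, "homology_artifact")

    if any(len(r["spliced_seq"]) < config.read_length for r in rows):
        raise ConfigError("read_length exceeds a planted circle's length")

    # ---- per-sample support, fold changes, host coupling --------------
    df = pd.DataFrame(rows)
    n, npg = config.n_samples, config.n_samples_per_group
    lo, hi = config.support_range
    base = rng.integers(lo, hi + 1, size=(len(df), n))
    fc = np.ones(len(df))
    cds_idx = shuffled(list(df.index[df.origin == "CDS"]))
    fc[cds_idx[:config.n_circ_up]] = config.circ_fold_change
    dn_sel = cds_idx[config.n_circ_up:config.n_circ_up + config.n_circ_down]
    fc[dn_sel] = 1.0 / config.circ_fold_change
    support = base.astype(float)
    # "up" scales the second group; "down" scales the FIRST group up, so
    # the minimum planted support stays at `lo` everywhere
    for r in range(len(df)):
        if fc[r] > 1:
            support[r, npg:] *= fc[r]
        elif fc[r] < 1:
            support[r, :npg] /= fc[r]
    support = np.rint(support).astype(int)
    df["fold_change"] = fc

    gene_ids = [g.gene_id for g in genome.genes]
    gbase = rng.integers(*config.gene_count_range, size=len(gene_ids))
    factors = rng.lognormal(0.0, config.sample_cv, size=(len(gene_ids), n))
    gfc = np.ones(len(gene_ids))
    reg_idx = [k for k, g in enumerate(gene_ids) if g.startswith("GENE")]
    for k in reg_idx[:config.n_gene_up]:
        gfc[k] = config.gene_fold_change
    for k in reg_idx[config.n_gene_up:
                     config.n_gene_up + config.n_gene_down]:
        gfc[k] = 1.0 / config.gene_fold_change
    gcounts = gbase[:, None] * factors
    gcounts[:, npg:] *= gfc[:, None]
    gcounts = np.rint(gcounts).astype(int)
    gene_counts = pd.DataFrame(gcounts, index=gene_ids,
                               columns=config.sample_ids)
    df["planted_gene_fc"] = [
        gfc[gene_ids.index(h.split(",")[0])] if h else 1.0
        for h in df.host_genes]

    coupled = [r for r in df.index
               if df.loc[r, "origin"] == "CDS" and fc[r] == 1.0]
    coupled = shuffled(coupled)[:config.n_coupled_circ]
    df["coupled"] = False
    max_distinct = config.read_length - 2 * config.min_overhang + 1
    for r in coupled:
        host = df.loc[r, "host_genes"].split(",")[0]
        f = factors[gene_ids.index(host)]
        support[r] = np.maximum(lo, np.rint(base[r].mean() * f)).astype(int)
        df.loc[r, "coupled"] = True
    support = np.minimum(support, max_distinct)
    for si, s in enumerate(config.sample_ids):
        df[f"support_{s}"] = support[:, si]

    genome.sequences["chrS"] = chrom_arr.tobytes().decode()
    df["spliced_seq"] = [_seq_from_map(genome.sequences["chrS"],
                                       r["gmap"], r["strand"])
                         for _, r in df.iterrows()]
    df["spliced_length"] = df["spliced_seq"].str.len()
    df["truth_name"] = [f"truth_circ_{k + 1}" for k in range(len(df))]
    return TruthTable(circs=df, gene_counts=gene_counts,
                      mirna_sites=pd.DataFrame(
                          columns=["circ", "mirna", "site_type", "count"]),
                      mirnas=pd.DataFrame(columns=["id", "sequence"]),
                      mirna_targets=pd.DataFrame(columns=["mirna", "gene"]))


# ------------------------------------------------------------------ miRNA sites

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_RNA2DNA = str.maketrans("U", "T")


def site_pattern(mature_rna: str, site_type: str) -> str:
    """DNA pattern on the target that the given canonical site type matches.

    ``S`` is the reverse complement of the 7-nt seed (miRNA positions 2-8).
    8mer = S+A; 7mer-m8 = S; 7mer-A1 = S[1:]+A; 6mer = S[1:].
    """
    seed = mature_rna[1:8].translate(_RNA2DNA)
    S = revcomp(seed)
    return {"8mer": S + "A", "7mer-m8": S,
            "7mer-A1": S[1:] + "A", "6mer": S[1:]}[site_type]


def make_mirna_panel(config: SimConfig) -> pd.DataFrame:
    """Toy panel of 22-nt mature miRNA sequences (RNA, 5'->3')."""
    rng = np.random.default_rng(config.seed + 2)
    rows, seen = [], set()
    while len(rows) < config.n_mirnas:
        seq = "".join("ACGU"[b]
                      for b in rng.integers(0, 4, config.mirna_length))
        if seq[1:8] in seen:
            continue
        seen.add(seq[1:8])
        rows.append({"id": f"miR-t{len(rows) + 1}", "sequence": seq})
    return pd.DataFrame(rows)


def _naive_site_count(seq: str, mature: str,
                      counted=SITE_TYPES[:3]) -> dict[str, int]:
    """Plain circular recount used only to freeze truth counts."""
    L = len(seq)
    scan = seq + seq[:7]
    counts = {t: 0 for t in SITE_TYPES}
    for p in range(L):
        for t in SITE_TYPES:
            pat = site_pattern(mature, t)
            if scan[p:p + len(pat)] == pat:
                if t in counted:
                    counts[t] += 1
                break
    return counts


def plant_mirna_sites(genome: GenomeBundle, truth: TruthTable,
                      config: SimConfig,
                      requests: list[tuple[int, int, str, int, bool]] | None
                      = None) -> TruthTable:
    """Inject seed-match sites into selected circRNA sequences.

    ``requests``: (circ row index, mirna index, site_type, n_sites,
    include_junction_spanning).  Defaults plant a clear top-tier sponge
    (12 sites, one wrapping the back-splice), a boundary candidate
    (exactly 5 sites) and a sub-threshold circ (3 sites) on three
    single-gene circles with distinct hosts.  Sites are written back into
    the genome through the exon coordinate map so reads and downstream
    splicing see them; truth counts are then frozen by a naive circular
    recount on the final sequences.
    """
    rng = np.random.default_rng(config.seed + 3)
    panel = make_mirna_panel(config)
    truth.mirnas = panel
    df = truth.circs
    chrom_arr = np.frombuffer(genome.sequences["chrS"].encode(),
                              dtype=np.uint8).copy()

    if requests is None:
        cand = [r for r in df.index
                if df.loc[r, "origin"] == "CDS"
                and df.loc[r, "fold_change"] == 1.0
                and df.loc[r, "spliced_length"] >= 420]
        hosts_seen, chosen = set(), []
        for r in cand:
            h = df.loc[r, "host_genes"]
            if h not in hosts_seen:
                hosts_seen.add(h)
                chosen.append(r)
            if len(chosen) == 3:
                break
        if len(chosen) < 3:
            raise ConfigError("no suitable circles for miRNA site planting")
        requests = [(chosen[0], 0, "7mer-m8", 12, True),
                    (chosen[1], 1, "8mer", 5, False),
                    (chosen[2], 2, "7mer-A1", 3, False)]

    for (ri, mi, stype, n_sites, with_wrap) in requests:
        row = df.loc[ri]
        seq = list(row["spliced_seq"])
        gmap, strand, L = row["gmap"], row["strand"], len(row["spliced_seq"])
        pat = site_pattern(panel.loc[mi, "sequence"], stype)
        w = len(pat)
        if n_sites * (w + 2) > L - 2 * w:
            raise ConfigError("requested sites exceed sequence capacity")
        taken: list[tuple[int, int]] = []

        def free(a, b):
            return all(b + 1 <= ta or a >= tb + 1 for ta, tb in taken)

        positions = []
        if with_wrap:
            p = L - w // 2      # spans the back-splice (wraps position 0)
            positions.append(p)
            taken += [(p, L), (0, p + w - L)]
        guard = 0
        while len(positions) < n_sites and guard < 20_000:
            guard += 1
            p = int(rng.integers(0, L - w))
            if free(p, p + w):
                positions.append(p)
                taken.append((p, p + w))
        if len(positions) < n_sites:
            raise ConfigError("could not place requested sites")
        for p in positions:
            for off, b in enumerate(pat):
                q = (p + off) % L
                seq[q] = b
                chrom_arr[gmap[q]] = ord(b if strand == "+" else revcomp(b))
        df.loc[ri, "spliced_seq"] = "".join(seq)

    genome.sequences["chrS"] = chrom_arr.tobytes().decode()
    chrom = genome.sequences["chrS"]
    df["spliced_seq"] = [_seq_from_map(chrom, r["gmap"], r["strand"])
                         for _, r in df.iterrows()]
    site_rows = []
    for (ri, mi, stype, n_sites, _w) in requests:
        counts = _naive_site_count(df.loc[ri, "spliced_seq"],
                                   panel.loc[mi, "sequence"])
        for t, c in counts.items():
            site_rows.append({"circ": df.loc[ri, "truth_name"],
                              "mirna": panel.loc[mi, "id"],
                              "site_type": t, "count": c,
                              "planted": n_sites if t == stype else 0})
    truth.mirna_sites = pd.DataFrame(site_rows)

    # toy target lists: each planted-sponge miRNA targets the planted
    # down-regulated genes plus one null gene
    gene_ids = list(truth.gene_counts.index)
    reg = [g for g in gene_ids if g.startswith("GENE")]
    dn = reg[config.n_gene_up:config.n_gene_up + config.n_gene_down]
    tgt_rows = [{"mirna": panel.loc[mi, "id"], "gene": g}
                for mi in range(3) for g in dn + [reg[-1 - mi]]]
    truth.mirna_targets = pd.DataFrame(tgt_rows)
    return truth


# ------------------------------------------------------------------ reads

def simulate_reads(genome: GenomeBundle, truth: TruthTable,
                   config: SimConfig) -> dict[str, list[tuple[str, str]]]:
    """Per-sample single-end reads with truth-encoded ids.

    Linear reads are windows of spliced transcript sequences, counts per
    the gene truth table.  Each planted circle gets exactly its planted
    number of distinct back-splice-spanning reads (junction overlapped by
    at least ``min_overhang`` nt on both sides) plus a few background
    circular reads that do not cross the junction.  Read ids encode
    provenance: ``<sample>|lin|<gene>|i``, ``<sample>|span|<circ>|i``,
    ``<sample>|int|<circ>|i``.
    """
    rng = np.random.default_rng(config.seed + 4)
    RL = config.read_length
    if any(truth.circs.spliced_length < RL):
        raise ConfigError("read_length exceeds a planted circle's length")
    transcripts = {g.gene_id: g.spliced_sequence(genome.sequences)
                   for g in genome.genes}

    def maybe_err(read: str) -> str:
        if config.error_rate <= 0:
            return read
        arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
        for i in np.nonzero(rng.random(len(arr)) < config.error_rate)[0]:
            choices = BASES[BASES != arr[i]]
            arr[i] = choices[rng.integers(0, len(choices))]
        return arr.tobytes().decode()

    out: dict[str, list[tuple[str, str]]] = {}
    for s in config.sample_ids:
        reads: list[tuple[str, str]] = []
        for gid, tseq in transcripts.items():
            n = int(truth.gene_counts.loc[gid, s])
            starts = rng.integers(0, len(tseq) - RL, size=n)
            for i, p in enumerate(starts):
                reads.append((f"{s}|lin|{gid}|{i}",
                              maybe_err(tseq[p:p + RL])))
        for r in truth.circs.itertuples():
            cseq = r.spliced_seq
            L = len(cseq)
            doubled = cseq + cseq
            sup = int(getattr(r, f"support_{s}"))
            offs = rng.choice(
                np.arange(config.min_overhang, RL - config.min_overhang + 1),
                size=sup, replace=False)
            for i, o in enumerate(offs):
                start = L - int(o)
                reads.append((f"{s}|span|{r.truth_name}|{i}",
                              maybe_err(doubled[start:start + RL])))
            if L > RL:
                nbg = config.background_reads_per_circ
                for i, p in enumerate(rng.integers(0, L - RL, size=nbg)):
                    reads.append((f"{s}|int|{r.truth_name}|{i}",
                                  maybe_err(cseq[p:p + RL])))
        out[s] = reads
        truth.read_totals[s] = len(reads)
    return out


# ------------------------------------------------------------------ fixture

@dataclass
class Fixture:
    """In-memory synthetic dataset: genome, truth, reads, config."""

    config: SimConfig
    genome: GenomeBundle
    truth: TruthTable
    reads: dict[str, list[tuple[str, str]]]


def make_fixture(config: SimConfig | None = None) -> Fixture:
    """Generate the full default fixture in memory."""
    config = config or SimConfig()
    genome = generate_genome(config)
    truth = plant_circrnas(genome, config)
    truth = plant_mirna_sites(genome, truth, config)
    reads = simulate_reads(genome, truth, config)
    return Fixture(config, genome, truth, reads)


def write_fixture(fix: Fixture, outdir) -> Path:
    """Write the fixture to disk (FASTA/GTF/FASTQ/TSVs + config YAML)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(fix.genome.sequences, outdir / "genome.fa")
    write_gtf(fix.genome.genes, outdir / "annotation.gtf")
    write_sample_sheet(fix.config.groups, outdir / "samples.tsv")
    for s, reads in fix.reads.items():
        write_fastq(reads, outdir / f"{s}.fastq")
    truth = fix.truth
    truth.circs.drop(columns=["gmap"]).to_csv(
        outdir / "truth_circs.tsv", sep="\t", index=False)
    truth.gene_counts.to_csv(outdir / "truth_gene_counts.tsv", sep="\t")
    truth.mirna_sites.to_csv(outdir / "truth_sites.tsv", sep="\t",
                             index=False)
    truth.mirnas.to_csv(outdir / "mirnas.tsv", sep="\t", index=False)
    truth.mirna_targets.to_csv(outdir / "targets.tsv", sep="\t", index=False)
    pd.Series(truth.read_totals).rename("total_reads").to_csv(
        outdir / "truth_read_totals.tsv", sep="\t")
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(fix.config).items()}
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return outdir


# ------------------------------------------------------------ DE/corr fixtures

def simulate_count_matrix(n_features: int, n_planted: int, fold_change: float,
                          phi: float, n_per_group: int = 5,
                          mean_low: float = 20.0, mean_high: float = 200.0,
                          seed: int = 0):
    """NB count matrix with planted two-group fold changes.

    Feature means are log-uniform in [mean_low, mean_high]; the first
    ``n_planted`` features get the fold change applied to group B
    (alternating up/down).  Returns (counts, truth_de) with truth_de in
    {+1, -1, 0} per feature.
    """
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.uniform(np.log(mean_low), np.log(mean_high), n_features))
    truth = np.zeros(n_features, dtype=int)
    truth[:n_planted:2] = 1
    truth[1:n_planted:2] = -1
    n = 2 * n_per_group
    muM = np.tile(mu[:, None], (1, n))
    muM[truth == 1, n_per_group:] *= fold_change
    muM[truth == -1, n_per_group:] /= fold_change
    lam = rng.gamma(1.0 / phi, phi * muM) if phi > 0 else muM
    counts = rng.poisson(lam)
    return counts, truth


def simulate_coupled_expression(n_pairs: int = 50, n_samples: int = 10,
                                coupling_noise: float = 0.15,
                                seed: int = 0):
    """Paired circ/host expression with planted coupling.

    Each host gene gets a lognormal per-sample profile; the paired circ
    follows it up to multiplicative noise.  An equal number of decoy
    genes with independent profiles is included for the random-pair
    comparison.  Returns (circ_df, gene_df, pairs); gene_df rows are
    hosts followed by decoys.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1}" for i in range(n_samples)]
    host = rng.lognormal(3.0, 0.8, size=(n_pairs, n_samples))
    circ = host * rng.lognormal(0.0, coupling_noise, size=host.shape) * \
        rng.lognormal(-1.0, 0.1, size=(n_pairs, 1))
    decoy = rng.lognormal(3.0, 0.8, size=(n_pairs, n_samples))
    circ_df = pd.DataFrame(circ, index=[f"circ_{i}" for i in range(n_pairs)],
                           columns=samples)
    gene_df = pd.DataFrame(
        np.vstack([host, decoy]),
        index=[f"host_{i}" for i in range(n_pairs)] +
              [f"decoy_{i}" for i in range(n_pairs)],
        columns=samples)
    pairs = {f"circ_{i}": f"host_{i}" for i in range(n_pairs)}
    return circ_df, gene_df, pairs
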