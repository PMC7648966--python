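"""Origin assignment, circular sequence splicing, naming, feature stats."""

from collections import Counter

import pytest

from circheart.annotate import (annotate_junctions, assign_origin,
                                feature_stats, splice_circ_sequence)
from circheart.models import BackspliceJunction, GeneModel, GenomeBundle, revcomp


def _gene(gene_id="g1", strand="+", chrom="c"):
    """Six-exon gene; CDS spans exons 3..4 fully and nothing else."""
    ivs = [(10, 20), (30, 40), (50, 60), (70, 80), (90, 100), (110, 120)]
    exons = tuple(ivs) if strand == "+" else tuple(ivs[::-1])
    return GeneModel(gene_id, chrom, strand, exons,
                     cds_ranges=((50, 60), (70, 80)))


class TestAssignOrigin:
    def test_cds_circle_with_exact_boundaries(self):
        g = _gene()
        j = BackspliceJunction("c", 50, 80, "+")
        call = assign_origin(j, [g])
        assert call.origin == "CDS"
        assert call.boundary_exact
        assert call.acceptor_exon == 3 and call.donor_exon == 4

    def test_utr_and_mixed_circles(self):
        g = _gene()
        assert assign_origin(BackspliceJunction("c", 10, 40, "+"),
                             [g]).origin == "UTR"
        assert assign_origin(BackspliceJunction("c", 30, 60, "+"),
                             [g]).origin == "UTR-CDS"

    def test_intronic_when_an_end_is_not_exonic(self):
        g = _gene()
        assert assign_origin(BackspliceJunction("c", 22, 45, "+"),
                             [g]).origin == "intronic"
        assert assign_origin(BackspliceJunction("c", 30, 45, "+"),
                             [g]).origin == "intronic"

    def test_intergenic_when_outside_all_genes(self):
        g = _gene()
        call = assign_origin(BackspliceJunction("c", 150, 300, "+"), [g])
        assert call.origin == "intergenic"
        assert call.host_genes == ()

    def test_two_gene_requires_same_strand_adjacency(self):
        g1 = _gene("g1")
        shift = 200
        ivs = [(a + shift, b + shift) for a, b in
               [(10, 20), (30, 40), (50, 60), (70, 80), (90, 100),
                (110, 120)]]
        g2 = GeneModel("g2", "c", "+", tuple(ivs),
                       cds_ranges=tuple(ivs[2:4]))
        j = BackspliceJunction("c", 70, 240, "+")  # g1 exon4 .. g2 exon2
        call = assign_origin(j, [g1, g2])
        assert call.origin == "two-gene"
        assert call.host_genes == ("g1", "g2")
        assert call.acceptor_exon == 4 and call.donor_exon == 2
        # an intervening gene breaks adjacency
        g3 = GeneModel("g3", "c", "+", ((150, 160), (170, 180)))
        assert assign_origin(j, [g1, g2, g3]).origin != "two-gene"

    def test_minus_strand_acceptor_exon_is_transcription_indexed(self):
        g = _gene(strand="-")
        j = BackspliceJunction("c", 50, 80, "-")
        call = assign_origin(j, [g])
        # transcription order runs right to left: exon 3 = (70, 80)
        assert call.origin == "CDS"
        assert call.acceptor_exon == 3 and call.donor_exon == 4

    def test_fixture_origins_match_truth(self, fix, result):
        truth = fix.truth.circs.set_index(
            ["chrom", "start", "end", "strand"])["origin"]
        for r in result.records:
            key = r.junction.key
            assert r.origin == truth.loc[key], key


class TestSpliceSequence:
    def test_exon_concatenation(self):
        seq = "A" * 10 + "AAA" + "T" * 10 + "GGG" + "C" * 10 + "CCC" + "G" * 10
        g = GeneModel("g", "c", "+", ((10, 13), (23, 26), (36, 39)))
        genome = GenomeBundle({"c": seq})
        j = BackspliceJunction("c", 10, 39, "+")
        call = assign_origin(j, [g])
        assert splice_circ_sequence(j, call, genome) == "AAAGGGCCC"

    def test_minus_strand_is_reverse_complement_in_transcription_order(self):
        seq = "A" * 10 + "AAA" + "T" * 10 + "GGG" + "C" * 10 + "CCC" + "G" * 10
        g = GeneModel("g", "c", "-", ((36, 39), (23, 26), (10, 13)))
        genome = GenomeBundle({"c": seq})
        j = BackspliceJunction("c", 10, 39, "-")
        call = assign_origin(j, [g])
        assert splice_circ_sequence(j, call, genome) == \
            revcomp("CCC") + revcomp("GGG") + revcomp("AAA")

    def test_non_boundary_junction_falls_back_to_genomic_interval(self):
        g = _gene()
        genome = GenomeBundle({"c": "ACGT" * 100})
        j = BackspliceJunction("c", 22, 45, "+")
        call = assign_origin(j, [g])
        out = splice_circ_sequence(j, call, genome)
        assert out == genome.sequences["c"][22:45]
        assert len(out) == 23

    def test_fixture_sequences_match_truth(self, fix, result):
        truth = fix.truth.circs.set_index(
            ["chrom", "start", "end", "strand"])["spliced_seq"]
        for r in result.records:
            assert r.spliced_seq == truth.loc[r.junction.key]


class TestNaming:
    def test_single_gene_rank_by_coordinates(self, fix, result):
        by_gene = {}
        for r in result.records:
            if len(r.host_genes) == 1 and r.origin != "two-gene":
                by_gene.setdefault(r.host_genes[0], []).append(r)
        for gid, recs in by_gene.items():
            recs = sorted(recs, key=lambda r: (r.junction.start,
                                               r.junction.end))
            for n, r in enumerate(recs, 1):
                assert r.name == f"circ{gid}_{n}"

    def test_two_gene_naming_pattern(self, result):
        two = [r for r in result.records if r.origin == "two-gene"]
        assert two
        for r in two:
            g1, g2 = r.host_genes
            assert r.name.startswith(f"{g1}_e")
            assert f":{g2}_e" in r.name

    def test_intergenic_fallback_name(self, result):
        inter = [r for r in result.records if r.origin == "intergenic"]
        assert inter
        for r in inter:
            assert r.name == (f"circINTERGENIC_{r.junction.chrom}_"
                              f"{r.junction.start}")

    def test_names_are_unique(self, result):
        names = [r.name for r in result.records]
        assert len(names) == len(set(names))


class TestFeatureStats:
    def test_counting_against_brute_force_recount(self, fix, result):
        stats = feature_stats(result.records, fix.genome.genes)
        # per-gene distribution equals a hand recount
        per_gene = Counter()
        for r in result.records:
            for gid in r.host_genes:
                per_gene[gid] += 1
        expect = Counter(per_gene.values())
        got = dict(zip(stats["per_gene"]["circ_per_gene"],
                       stats["per_gene"]["n_genes"]))
        assert got == dict(expect)
        # origin classes partition the record set
        assert stats["size"]["origin"].notna().all()
        assert len(stats["size"]) == len(result.records)

    def test_acceptor_exon_distribution(self):
        g = _gene()
        genome = GenomeBundle({"c": "ACGT" * 100}, [g])
        j = BackspliceJunction("c", 30, 80, "+", {"s": 3})
        recs = annotate_junctions([j], genome)
        stats = feature_stats(recs, [g])
        acc = dict(zip(stats["acceptor_exon"]["exon_index"],
                       stats["acceptor_exon"]["n_circ"]))
        assert acc == {2: 1}
        npc = dict(zip(stats["exons_per_circ"]["n_exons"],
                       stats["exons_per_circ"]["n_circ"]))
        assert npc == {3: 1}

    def test_gene_exon_bin_table(self, fix, result):
        stats = feature_stats(result.records, fix.genome.genes)
        bg = stats["by_gene_exons"]
        # all fixture genes have 8-12 exons -> single bin "1-10" or "11-20"
        assert set(bg["exon_bin"]) <= {"1-10", "11-20"}
        total_mean = (bg["mean_circ_per_gene"] *
                      [sum(1 for g in fix.genome.genes
                           if (g.n_exons - 1) // 10 == b)
                       for b in bg["bin_order"]]).sum()
        host_slots = sum(len(r.host_genes) for r in result.records)
        assert abs(total_mean - host_slots) < 1e-9
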