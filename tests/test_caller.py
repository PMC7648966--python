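"""Junction caller: anchor index, linear alignment, back-splice calls."""

import numpy as np
import pytest

from circheart.caller import (CallStats, aggregate_junctions, align_linear,
                              build_index, call_backsplice,
                              call_sample_junctions)
from circheart.models import GenomeBundle, revcomp


def _toy_genome():
    """A + strand 'gene' with two exons and a planted back-splice.

    Layout (coordinates): exon1 = [10, 60), intron with GT..AG, exon2 =
    [100, 150).  A circle over both exons has acceptor = 10, donor = 150.
    """
    rng = np.random.default_rng(42)
    arr = list("ACGT"[i] for i in rng.integers(0, 4, 200))
    arr[60:62] = "GT"      # donor signal after exon1
    arr[98:100] = "AG"     # acceptor signal before exon2
    arr[150:152] = "GT"    # donor signal after exon2
    arr[8:10] = "AG"       # acceptor signal before exon1
    seq = "".join(arr)
    return GenomeBundle({"chr1": seq}), (10, 60), (100, 150)


class TestIndex:
    def test_palindromic_repeat_is_not_unique(self):
        g = GenomeBundle({"c": "ACGTACGT"})
        idx = build_index(g, k=4)
        occ = idx.occurrences("ACGT")
        # plus strand positions 0 and 4, and ACGT is its own revcomp
        assert len(occ) == 4
        assert idx.unique_occurrence("ACGT") is None

    def test_absent_kmer_has_no_occurrences(self):
        g = GenomeBundle({"c": "AAAAAAAA"})
        idx = build_index(g, k=4)
        assert idx.occurrences("CCCC") == []

    def test_lookup_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        g = GenomeBundle({"c": seq})
        k = 12
        idx = build_index(g, k=k)
        rc = revcomp(seq)
        for _ in range(100):
            p = int(rng.integers(0, len(seq) - k))
            kmer = seq[p:p + k]
            expect = []
            for strand, s in (("+", seq), ("-", rc)):
                q = s.find(kmer)
                while q != -1:
                    expect.append(("c", strand, q))
                    q = s.find(kmer, q + 1)
            assert sorted(idx.occurrences(kmer)) == sorted(expect)

    def test_k_larger_than_chromosome_rejected(self):
        with pytest.raises(ValueError):
            build_index(GenomeBundle({"c": "ACGTACGTAC"}), k=20)

    def test_n_containing_kmers_skipped(self):
        g = GenomeBundle({"c": "ACGTNACGTACG"})
        idx = build_index(g, k=8)
        assert all("N" not in k for k in idx.lookup)


class TestAlignLinear:
    def test_genomic_substring_maps(self):
        g, e1, e2 = _toy_genome()
        idx = build_index(g, k=10)
        seq = g.sequences["chr1"]
        mapped, unmapped = align_linear([("r1", seq[20:60])], idx, g)
        assert mapped == 1 and unmapped == []

    def test_reverse_strand_read_maps(self):
        g, e1, e2 = _toy_genome()
        idx = build_index(g, k=10)
        read = revcomp(g.sequences["chr1"][20:60])
        mapped, unmapped = align_linear([("r1", read)], idx, g)
        assert mapped == 1

    def test_backsplice_spanning_read_is_unmapped(self, fix):
        from circheart.caller import build_index as bi
        idx = bi(fix.genome, k=20)
        s = fix.config.sample_ids[0]
        span = [(rid, seq) for rid, seq in fix.reads[s] if "|span|" in rid]
        mapped, unmapped = align_linear(span[:10], idx, fix.genome)
        assert mapped == 0 and len(unmapped) == 10

    def test_raising_mm_never_unmaps(self):
        g, _, _ = _toy_genome()
        idx = build_index(g, k=10)
        seq = g.sequences["chr1"]
        reads = [("exact", seq[20:60]),
                 ("onesub", seq[100:140][:20] + "A" + seq[121:140])]
        m0, u0 = align_linear(reads, idx, g, mm=0)
        m2, u2 = align_linear(reads, idx, g, mm=2)
        assert m2 >= m0
        assert {r[0] for r in u2} <= {r[0] for r in u0}


class TestCallBacksplice:
    def _span_read(self, g, e1, e2, left=25, right=25):
        """Read = last `left` nt of exon2 ++ first `right` nt of exon1."""
        seq = g.sequences["chr1"]
        return seq[e2[1] - left:e2[1]] + seq[e1[0]:e1[0] + right]

    def test_constructed_backsplice_read_yields_planted_junction(self):
        g, e1, e2 = _toy_genome()
        idx = build_index(g, k=10)
        read = self._span_read(g, e1, e2)
        calls = call_backsplice([("r", read)], idx, g)
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (e1[0], e2[1])
        assert calls[0].strand == "+"

    def test_offset_backsplice_reads_agree_on_coordinates(self):
        g, e1, e2 = _toy_genome()
        idx = build_index(g, k=10)
        keys = set()
        for left in (20, 30, 35):
            read = self._span_read(g, e1, e2, left, 50 - left)
            calls = call_backsplice([("r", read)], idx, g)
            keys |= {c.key for c in calls}
        assert keys == {("chr1", e1[0], e2[1], "+")}

    def test_minus_strand_junction_reported_on_forward_coordinates(self):
        g, e1, e2 = _toy_genome()
        # present the same molecule from the opposite strand: signals CT/AC
        seq = list(g.sequences["chr1"])
        seq[60:62] = "CT"
        seq[98:100] = "AC"
        seq[150:152] = "CT"
        seq[8:10] = "AC"
        g2 = GenomeBundle({"chr1": "".join(seq)})
        circ = revcomp(g2.sequences["chr1"][100:150]) + \
            revcomp(g2.sequences["chr1"][10:60])
        read = circ[len(circ) - 75:len(circ) - 75 + 50]  # crosses junction
        # junction on the minus strand: acceptor at exon2 (genomic end),
        # read = tail of exon1-revcomp ++ head of exon2-revcomp
        read = (revcomp(g2.sequences["chr1"][10:35]) +
                revcomp(g2.sequences["chr1"][125:150]))
        idx = build_index(g2, k=10)
        calls = call_backsplice([("r", read)], idx, g2)
        assert len(calls) == 1
        assert calls[0].strand == "-"
        assert (calls[0].start, calls[0].end) == (10, 150)

    def test_forward_order_anchors_give_no_call(self):
        g, e1, e2 = _toy_genome()
        idx = build_index(g, k=10)
        seq = g.sequences["chr1"]
        # ordinary linear splice read: end of exon1 ++ start of exon2
        read = seq[e1[1] - 25:e1[1]] + seq[e2[0]:e2[0] + 25]
        st = CallStats()
        assert call_backsplice([("r", read)], idx, g, stats=st) == []
        assert st.dropped["forward_order"] == 1

    def test_non_unique_anchor_gives_no_call(self):
        g, e1, e2 = _toy_genome()
        seq = g.sequences["chr1"]
        # duplicate the read's first-anchor sequence elsewhere
        dup = seq[e2[1] - 25:e2[1] - 15]
        g2 = GenomeBundle({"chr1": seq + "T" * 5 + dup + "A" * 5})
        idx = build_index(g2, k=10)
        read = self._span_read(g2, e1, e2)
        st = CallStats()
        assert call_backsplice([("r", read)], idx, g2, stats=st) == []
        assert st.dropped["anchor_not_unique"] == 1

    def test_missing_splice_signal_drops_read_unless_disabled(self):
        g, e1, e2 = _toy_genome()
        seq = list(g.sequences["chr1"])
        seq[150:152] = "TT"    # destroy the donor GT
        g2 = GenomeBundle({"chr1": "".join(seq)})
        idx = build_index(g2, k=10)
        read = self._span_read(g2, e1, e2)
        assert call_backsplice([("r", read)], idx, g2) == []
        calls = call_backsplice([("r", read)], idx, g2,
                                require_signal=False)
        assert len(calls) == 1

    def test_strand_consistency_of_reported_signal(self, fix, result):
        """Every emitted junction's coordinates carry the canonical signal
        for its reported strand."""
        chrom = fix.genome.sequences["chrS"]
        for j in result.junctions:
            if j.strand == "+":
                assert chrom[j.start - 2:j.start] == "AG"
                assert chrom[j.end:j.end + 2] == "GT"
            else:
                assert chrom[j.start - 2:j.start] == "AC"
                assert chrom[j.end:j.end + 2] == "CT"


class TestAggregate:
    def test_duplicate_sequences_collapse(self):
        g, e1, e2 = _toy_genome()
        idx = build_index(g, k=10)
        seq = g.sequences["chr1"]
        reads = [("a", seq[e2[1] - 25:e2[1]] + seq[e1[0]:e1[0] + 25]),
                 ("b", seq[e2[1] - 30:e2[1]] + seq[e1[0]:e1[0] + 20]),
                 ("c", seq[e2[1] - 20:e2[1]] + seq[e1[0]:e1[0] + 30]),
                 ("dup", seq[e2[1] - 25:e2[1]] + seq[e1[0]:e1[0] + 25])]
        calls = {"s1": call_backsplice(reads, idx, g)}
        out = aggregate_junctions(calls)
        assert len(out) == 1
        assert out[0].support == {"s1": 3}

    def test_single_read_everywhere_is_dropped(self):
        g, e1, e2 = _toy_genome()
        idx = build_index(g, k=10)
        seq = g.sequences["chr1"]
        read = seq[e2[1] - 25:e2[1]] + seq[e1[0]:e1[0] + 25]
        calls = {s: call_backsplice([("r", read)], idx, g)
                 for s in ("s1", "s2", "s3")}
        assert aggregate_junctions(calls) == []

    def test_two_reads_in_one_sample_is_kept(self):
        g, e1, e2 = _toy_genome()
        idx = build_index(g, k=10)
        seq = g.sequences["chr1"]
        reads = [("a", seq[e2[1] - 25:e2[1]] + seq[e1[0]:e1[0] + 25]),
                 ("b", seq[e2[1] - 30:e2[1]] + seq[e1[0]:e1[0] + 20])]
        calls = {"s1": call_backsplice(reads, idx, g), "s2": []}
        out = aggregate_junctions(calls)
        assert len(out) == 1 and out[0].support == {"s1": 2}


def test_fixture_recall_and_support_are_exact(fix, result):
    """On the error-free fixture every planted junction is recovered with
    exactly its planted per-sample support, and nothing else is called."""
    truth = fix.truth.circs
    sup_cols = [c for c in truth.columns if c.startswith("support_")]
    planted = {(r.chrom, int(r.start), int(r.end), r.strand):
               {c[len("support_"):]: int(getattr(r, c)) for c in sup_cols}
               for r in truth.itertuples()}
    found = {j.key: j.support for j in result.junctions}
    assert set(found) == set(planted)
    for key, sup in found.items():
        for s, v in planted[key].items():
            assert sup.get(s, 0) == v
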