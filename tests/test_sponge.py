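"""Seed-site counting on circular sequences and network construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circheart.sponge import (MiRNA, SITE_TYPES, build_network,
                              circular_scan_sequence,
                              release_of_repression, seed_sites,
                              site_count_table, sponge_candidates)


def oracle_sites(seq, mirna, include_6mer=False):
    """Naive per-position circular pattern scan with type precedence.

    Independent re-statement of the counting rule: for each start on the
    circle test 8mer, 7mer-m8, 7mer-A1 (and optionally 6mer) in order and
    record the first match."""
    pats = mirna.site_patterns()
    types = SITE_TYPES if include_6mer else SITE_TYPES[:3]
    L = len(seq)
    big = seq + seq     # full doubling: any site fits
    out = []
    for p in range(L):
        for t in types:
            if big[p:p + len(pats[t])] == pats[t]:
                out.append((p, t))
                break
    return out


def _mirna(seed7, mid="m"):
    """Build a MiRNA whose positions 2-8 equal seed7 (RNA)."""
    mature = "A" + seed7 + "AGCUAGCUAGCUAG"
    return MiRNA(mid, mature)


class TestPatterns:
    def test_site_patterns_from_seed(self):
        m = _mirna("AGCAGCA")
        pats = m.site_patterns()
        assert pats["7mer-m8"] == "TGCTGCT"
        assert pats["8mer"] == "TGCTGCTA"
        assert pats["7mer-A1"] == "GCTGCTA"
        assert pats["6mer"] == "GCTGCT"

    def test_short_mature_rejected(self):
        with pytest.raises(ValueError):
            MiRNA("bad", "ACGUACG")

    def test_non_acgu_seed_rejected(self):
        with pytest.raises(ValueError):
            MiRNA("bad", "AXXXXXXXACGUACGUACGUAC")


class TestScanString:
    def test_appends_wraparound_prefix(self):
        assert circular_scan_sequence("AAACCC", 8) == "AAACCCAAACCC"
        s = "ACGT" * 5
        assert len(circular_scan_sequence(s, 8)) == len(s) + 7

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            circular_scan_sequence("")


class TestSeedSites:
    def test_8mer_precedence_at_shared_start(self):
        m = _mirna("AGCAGCA")   # S = TGCTGCT
        hits = seed_sites("AATGCTGCTAA", m)
        # TGCTGCT at position 2 followed by A: start 2 is an 8mer, never
        # double-counted as 7mer-m8; the nested 7mer-A1 at start 3 is a
        # distinct start and counts separately
        assert {(h.start, h.site_type) for h in hits} == \
            {(2, "8mer"), (3, "7mer-A1")}

    def test_7mer_m8_when_no_adjacent_A(self):
        m = _mirna("AGCAGCA")
        hits = seed_sites("AATGCTGCTCC", m)
        assert [h.site_type for h in hits] == ["7mer-m8"]

    def test_rna_input_transliterated(self):
        m = _mirna("AGCAGCA")
        hits = seed_sites("AAUGCUGCUCC", m)
        assert [h.site_type for h in hits] == ["7mer-m8"]

    def test_polyA_has_no_sites_for_gc_seed(self):
        m = _mirna("GCGCGCG")
        assert seed_sites("A" * 200, m, include_6mer=True) == []

    def test_junction_wrapping_site_detected(self):
        m = _mirna("AGCAGCA")   # 7mer-m8 pattern TGCTGCT
        seq = "CTGCT" + "A" * 50 + "TG"   # wraps: TG|CTGCT at start 55
        hits = seed_sites(seq, m)
        assert any(h.start == 55 for h in hits)

    def test_rotation_invariance_of_counts(self):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        m = _mirna("AGCAGCA")
        seq = seq[:40] + "TGCTGCTA" + seq[48:]   # ensure one site
        base = sorted(h.site_type for h in seed_sites(seq, m,
                                                      include_6mer=True))
        for rot in (1, 7, 123, 299):
            r = seq[rot:] + seq[:rot]
            got = sorted(h.site_type for h in seed_sites(r, m,
                                                         include_6mer=True))
            assert got == base

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seq=st.text(alphabet="ACGT", min_size=30, max_size=200),
           rot=st.integers(min_value=0, max_value=199),
           seed=st.text(alphabet="ACGU", min_size=7, max_size=7))
    def test_rotation_invariance_property(self, seq, rot, seed):
        """Counts per (miRNA, type) are invariant under any rotation of
        the circular sequence."""
        m = _mirna(seed)
        rot %= len(seq)
        rotated = seq[rot:] + seq[:rot]
        a = sorted(h.site_type
                   for h in seed_sites(seq, m, include_6mer=True))
        b = sorted(h.site_type
                   for h in seed_sites(rotated, m, include_6mer=True))
        assert a == b

    def test_agrees_with_oracle_on_random_sequences(self):
        rng = np.random.default_rng(1)
        mirnas = [MiRNA(f"m{i}", "".join("ACGU"[b] for b in
                                         rng.integers(0, 4, 22)))
                  for i in range(5)]
        for _ in range(30):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
            for m in mirnas:
                got = [(h.start, h.site_type)
                       for h in seed_sites(seq, m, include_6mer=True)]
                assert got == oracle_sites(seq, m, include_6mer=True)


class TestCandidates:
    def _sites(self, rows):
        return pd.DataFrame([{"circ": c, "mirna": m, "total": n}
                             for c, m, n in rows])

    def test_five_sites_is_candidate_but_not_top(self):
        s = self._sites([("c1", "m1", 5), ("c1", "m2", 0)])
        _, cand, top = sponge_candidates(s)
        assert list(cand.circ) == ["c1"]
        assert len(top) == 0

    def test_four_sites_is_excluded(self):
        s = self._sites([("c1", "m1", 4)])
        _, cand, _ = sponge_candidates(s)
        assert len(cand) == 0

    def test_twelve_sites_is_top_tier(self):
        s = self._sites([("c1", "m1", 12)])
        _, cand, top = sponge_candidates(s)
        assert list(top.circ) == ["c1"]

    def test_candidate_set_monotone_in_min_sites(self):
        s = self._sites([("c1", "m1", 5), ("c2", "m1", 7),
                         ("c3", "m2", 9)])
        sizes = [len(sponge_candidates(s, min_sites=k)[1])
                 for k in (4, 6, 8, 10)]
        assert sizes == sorted(sizes, reverse=True)

    def test_fixture_planted_sponges_recovered(self, fix, result):
        """The planted 12-site circ reaches the top tier; the planted
        5-site circ is a candidate; 3 sites is below threshold."""
        truth = fix.truth
        key2name = {r.junction.key: r.name for r in result.records}
        t = truth.circs.set_index("truth_name")
        planted_tot = truth.mirna_sites.groupby("circ")["count"].sum()
        cand = set(result.candidates.circ)
        top = set(result.top_tier.circ)
        for tname, total in planted_tot.items():
            row = t.loc[tname]
            name = key2name[(row.chrom, int(row.start), int(row.end),
                             row.strand)]
            assert (name in cand) == (total >= 5)
            assert (name in top) == (total >= 10)


class TestNetwork:
    def test_edge_counting(self):
        sites = pd.DataFrame([{"circ": "C", "mirna": "m", "total": 6}])
        cand = pd.DataFrame([{"circ": "C", "max_sites": 6,
                              "best_mirna": "m"}])
        targets = pd.DataFrame([{"mirna": "m", "gene": "g1"},
                                {"mirna": "m", "gene": "g2"}])
        G, edges = build_network(sites, cand, targets)
        assert len(edges) == 3
        assert (edges.interaction == "circ-miR").sum() == 1
        assert (edges.interaction == "miR-mRNA").sum() == 2

    def test_empty_candidates_give_empty_network(self):
        sites = pd.DataFrame([{"circ": "C", "mirna": "m", "total": 2}])
        cand = pd.DataFrame(columns=["circ", "max_sites", "best_mirna"])
        targets = pd.DataFrame([{"mirna": "m", "gene": "g"}])
        _, edges = build_network(sites, cand, targets)
        assert len(edges) == 0

    def test_unknown_mirna_target_rows_skipped(self):
        sites = pd.DataFrame([{"circ": "C", "mirna": "m", "total": 6}])
        cand = pd.DataFrame([{"circ": "C", "max_sites": 6,
                              "best_mirna": "m"}])
        targets = pd.DataFrame([{"mirna": "unknown", "gene": "g"}])
        _, edges = build_network(sites, cand, targets)
        assert (edges.interaction == "miR-mRNA").sum() == 0

    def test_fixture_network_matches_truth_reconstruction(self, fix, result):
        """Every circ-miR edge corresponds to >= 5 sites in the site
        table, and every miR-mRNA edge to a planted target row."""
        edges = result.edges
        pair = result.site_table.groupby(["circ", "mirna"])["total"].sum()
        for e in edges[edges.interaction == "circ-miR"].itertuples():
            assert pair[(e.source, e.target)] == e.weight >= 5
        planted = set(map(tuple, fix.truth.mirna_targets.to_numpy()))
        for e in edges[edges.interaction == "miR-mRNA"].itertuples():
            assert (e.source, e.target) in planted

    def test_release_of_repression_report(self):
        edges = pd.DataFrame([
            {"source": "C", "target": "m", "interaction": "circ-miR",
             "weight": 6, "target_regulation": ""},
            {"source": "m", "target": "g", "interaction": "miR-mRNA",
             "weight": 1, "target_regulation": "down"}])
        circ_de = pd.DataFrame([{"feature_id": "C", "direction": "down"}])
        rep = release_of_repression(edges, circ_de)
        assert len(rep) == 1
        assert rep.iloc[0].tolist() == ["C", "m", "g"]
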