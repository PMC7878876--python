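import numpy as np
import pandas as pd
import pytest

from ssrscape.detect import SSRRecord
from ssrscape.io import read_gff3, write_gff3
from ssrscape.ortholog import (GeneModel, event_summary,
                               gene_models_from_gff,
                               gene_models_to_gff_frame,
                               map_ssrs_to_features, match_ortholog_ssrs)


def ssr(start, end, motif="AG", seq_id="chr1"):
    period = len(motif)
    return SSRRecord(seq_id, start, end, motif, period,
                     (end - start) / period, end - start)


def toy_gene(gene_id="g1", seq_id="chr1", strand="+", offset=0):
    """utr5(200) exon1(300) intron1(400) exon2(300) intron2(400)
    exon3(300) utr3(200), explicit introns, plus ordinals."""
    rows = []
    o = offset
    spans = [("five_prime_UTR", 200), ("exon", 300), ("intron", 400),
             ("exon", 300), ("intron", 400), ("exon", 300),
             ("three_prime_UTR", 200)]
    feats = []
    for ftype, width in spans:
        feats.append((ftype, o, o + width))
        o += width
    tx = gene_id + ".t1"
    rows.append((seq_id, "gene", offset, o, strand, gene_id, "",
                 f"ID={gene_id}"))
    rows.append((seq_id, "mRNA", offset, o, strand, tx, gene_id,
                 f"ID={tx};Parent={gene_id}"))
    for ftype, s, e in feats:
        rows.append((seq_id, ftype, s, e, strand, "", tx, f"Parent={tx}"))
    return pd.DataFrame(rows, columns=[
        "seq_id", "type", "start", "end", "strand", "id", "parent",
        "attrs"])


class TestGeneModels:
    def test_explicit_features_and_ordinals(self):
        gm, = gene_models_from_gff(toy_gene())
        by = {(f[0], f[3]): (f[1], f[2]) for f in gm.features}
        assert by[("intron", 1)] == (500, 900)
        assert by[("intron", 2)] == (1200, 1600)
        assert by[("exon", 3)] == (1600, 1900)

    def test_minus_strand_ordinals_count_from_right(self):
        gm, = gene_models_from_gff(toy_gene(strand="-"))
        by = {(f[0], f[3]): (f[1], f[2]) for f in gm.features}
        # intron 1 is the 5'-most = rightmost on the minus strand
        assert by[("intron", 1)] == (1200, 1600)
        assert by[("intron", 2)] == (500, 900)

    def test_introns_derived_from_exon_gaps(self):
        gff = toy_gene()
        gff = gff[gff["type"] != "intron"]
        gm, = gene_models_from_gff(gff)
        introns = sorted((f[1], f[2]) for f in gm.features
                         if f[0] == "intron")
        assert introns == [(500, 900), (1200, 1600)]

    def test_round_trip_through_gff3(self, tmp_path):
        gm, = gene_models_from_gff(toy_gene())
        path = tmp_path / "genes.gff3"
        write_gff3(gene_models_to_gff_frame([gm]), path)
        back, = gene_models_from_gff(read_gff3(path))
        assert sorted(back.features) == sorted(gm.features)

    def test_zero_length_gene_skipped(self):
        gff = toy_gene()
        gff.loc[gff["type"].isin(["exon", "intron", "five_prime_UTR",
                                  "three_prime_UTR"]), "end"] = \
            gff.loc[gff["type"].isin(["exon", "intron", "five_prime_UTR",
                                      "three_prime_UTR"]), "start"]
        assert gene_models_from_gff(gff) == []


class TestInventory:
    def test_feature_assignment_examples(self):
        genes = gene_models_from_gff(toy_gene())
        res = map_ssrs_to_features(
            [ssr(1300, 1340),     # inside intron 2
             ssr(5_000, 5_040),   # intergenic
             ssr(80, 120)],       # 5' UTR
            genes)
        inv = res["inventory"]["g1"]
        assert ("intron", 2) in [(f, o) for f, o, _ in inv]
        assert ("five_prime_UTR", 1) in [(f, o) for f, o, _ in inv]
        assert len(inv) == 2
        assert res["fraction_with_ssr"] == 1.0

    def test_largest_overlap_wins_at_boundaries(self):
        genes = gene_models_from_gff(toy_gene())
        res = map_ssrs_to_features([ssr(480, 540)], genes)  # 20 exon/40 intron
        (ftype, ordinal, _), = res["inventory"]["g1"]
        assert (ftype, ordinal) == ("intron", 1)

    def test_matches_all_pairs_brute_force(self, rng):
        gff = pd.concat([toy_gene("g1", offset=0),
                         toy_gene("g2", offset=3000),
                         toy_gene("g3", offset=6000, strand="-")],
                        ignore_index=True)
        genes = gene_models_from_gff(gff)
        ssrs = [ssr(int(s), int(s) + 40)
                for s in rng.integers(0, 9000, size=80)]
        res = map_ssrs_to_features(ssrs, genes)
        n_assigned = sum(len(v) for v in res["inventory"].values())
        # brute force: an SSR is assigned iff it overlaps a non-exon
        # feature or an exon (all gene bp is covered by features here)
        expected = 0
        for s in ssrs:
            hits = []
            for gm in genes:
                for ftype, fs, fe, o in gm.features:
                    if min(s.end, fe) - max(s.start, fs) > 0:
                        hits.append((gm.gene_id, ftype, o))
            expected += bool(hits)
        assert n_assigned == expected


class TestMatching:
    def inv(self, items, gene="g1"):
        return {"inventory": {gene: items}, "n_genes": 1,
                "n_genes_with_ssr": int(bool(items)),
                "fraction_with_ssr": float(bool(items))}

    pairs = pd.DataFrame({"gene_id_a": ["g1"], "gene_id_b": ["g1"]})

    def test_intron5_elongation_example(self):
        """(AG)n at intron 5 with 53 vs 421 motif repeats: elongated,
        ratio ~7.94."""
        a = self.inv([("intron", 5, ssr(0, 106, "AG"))])    # 53 repeats
        b = self.inv([("intron", 5, ssr(0, 842, "AG"))])    # 421 repeats
        events, skipped = match_ortholog_ssrs(a, b, self.pairs)
        e, = events
        assert skipped == 0
        assert e.event == "elongated"
        assert e.repeats_a == 53 and e.repeats_b == 421
        assert e.elongation_ratio == pytest.approx(421 / 53, rel=1e-6)
        assert e.elongation_ratio == pytest.approx(7.94, abs=0.01)

    def test_identical_inventories_conserved(self):
        items = [("intron", 1, ssr(0, 40)), ("three_prime_UTR", 1,
                                             ssr(100, 130, "AT"))]
        events, _ = match_ortholog_ssrs(self.inv(items), self.inv(items),
                                        self.pairs)
        assert [e.event for e in events] == ["conserved", "conserved"]

    def test_unmatched_become_insertions(self):
        a = self.inv([("intron", 1, ssr(0, 40))])
        b = self.inv([("intron", 1, ssr(0, 40)),
                      ("intron", 2, ssr(100, 160, "AT"))])
        events, _ = match_ortholog_ssrs(a, b, self.pairs)
        assert sorted(e.event for e in events) == ["conserved",
                                                   "inserted_b"]

    def test_swap_symmetry(self):
        a = self.inv([("intron", 1, ssr(0, 40)),
                      ("intron", 3, ssr(200, 260, "AT"))])
        b = self.inv([("intron", 1, ssr(0, 100)),
                      ("five_prime_UTR", 1, ssr(300, 330, "A"))])
        fwd, _ = match_ortholog_ssrs(a, b, self.pairs)
        rev, _ = match_ortholog_ssrs(b, a, self.pairs)
        swap = {"inserted_a": "inserted_b", "inserted_b": "inserted_a",
                "elongated": "contracted", "contracted": "elongated",
                "conserved": "conserved"}
        assert sorted(swap[e.event] for e in fwd) == \
            sorted(e.event for e in rev)

    def test_missing_gene_model_skipped(self):
        a = self.inv([("intron", 1, ssr(0, 40))], gene="gX")
        b = self.inv([("intron", 1, ssr(0, 40))])
        events, skipped = match_ortholog_ssrs(a, b, self.pairs)
        assert events == [] and skipped == 1

    def test_every_ssr_appears_in_exactly_one_event(self):
        a = self.inv([("intron", 1, ssr(0, 40)), ("intron", 1, ssr(60, 100)),
                      ("exon", 2, ssr(200, 240, "AT"))])
        b = self.inv([("intron", 1, ssr(0, 40))])
        events, _ = match_ortholog_ssrs(a, b, self.pairs)
        n_a = sum(1 for e in events if not np.isnan(e.repeats_a))
        n_b = sum(1 for e in events if not np.isnan(e.repeats_b))
        assert n_a == 3 and n_b == 1


def test_event_summary_counts_and_extremes():
    a = {"inventory": {"g1": [("intron", 2, ssr(0, 1352, "AT"))],
                       "g2": [("intron", 1, ssr(0, 40))]},
         "n_genes": 2, "n_genes_with_ssr": 2, "fraction_with_ssr": 1.0}
    b = {"inventory": {"g1": [("intron", 2, ssr(0, 24, "AT"))],
                       "g2": []},
         "n_genes": 2, "n_genes_with_ssr": 1, "fraction_with_ssr": 0.5}
    pairs = pd.DataFrame({"gene_id_a": ["g1", "g2"],
                          "gene_id_b": ["g1", "g2"]})
    events, _ = match_ortholog_ssrs(a, b, pairs)
    summ = event_summary(events)
    assert summ["by_event"]["contracted"] == 1
    assert summ["by_event"]["inserted_a"] == 1
    # the (AT)676-scale record tops the extreme list
    assert summ["extreme"][0].repeats_a == 676
    empty = event_summary([])
    assert empty["by_event"].sum() == 0
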