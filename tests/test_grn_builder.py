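from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from prc2net.expression_integration import DiffExprRecord
from prc2net.gene_annotation import GeneModel
from prc2net.grn_builder import (assemble_evidence, draft_grn,
                                 gene_set_enrichment, overlap_test, read_gmt,
                                 write_network_tables, write_sif)
from prc2net.occupancy_clustering import LossCall


def fisher_two_sided_oracle(a, b, c, d):
    """Exact rational enumeration over all tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(r1 + r2, c1)

    def pr(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return Fraction(0)
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    pobs = pr(a)
    total = sum(pr(x) for x in range(min(r1, c1) + 1) if pr(x) <= pobs)
    return float(min(total, Fraction(1)))


class TestOverlapTest:
    def test_identical_sets(self):
        uni = {f"g{i}" for i in range(100)}
        A = {f"g{i}" for i in range(10)}
        r = overlap_test(A, A, uni)
        assert r.overlap_fraction == 1.0
        assert r.table == (10, 0, 0, 90)
        assert r.pvalue == pytest.approx(fisher_two_sided_oracle(10, 0, 0, 90),
                                         abs=1e-12)

    def test_disjoint_sets(self):
        uni = {f"g{i}" for i in range(50)}
        A = {f"g{i}" for i in range(5)}
        B = {f"g{i}" for i in range(5, 12)}
        r = overlap_test(A, B, uni)
        assert r.overlap_fraction == 0.0 and r.a == 0

    def test_matches_enumeration_oracle_on_fixed_table(self):
        uni = {f"g{i}" for i in range(100)}
        A = {f"g{i}" for i in range(12)}          # a+b = 12
        B = {f"g{i}" for i in range(10)} | {f"g{i}" for i in range(12, 15)}
        r = overlap_test(A, B, uni)
        assert r.table == (10, 2, 3, 85)
        assert r.pvalue == pytest.approx(fisher_two_sided_oracle(10, 2, 3, 85),
                                         abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 200))
        uni = {f"g{i}" for i in range(n)}
        ids = sorted(uni)
        A = set(rng.choice(ids, size=rng.integers(0, n + 1), replace=False))
        B = set(rng.choice(ids, size=rng.integers(0, n + 1), replace=False))
        r = overlap_test(A, B, uni)
        assert r.pvalue == pytest.approx(
            fisher_two_sided_oracle(*r.table), abs=1e-12)
        assert 0 < r.pvalue <= 1.0

    def test_sets_must_be_in_universe(self):
        with pytest.raises(ValueError):
            overlap_test({"x"}, set(), {"a", "b"})


def _genes(n=5, spacing=20000):
    return [GeneModel(f"g{i}", "chr1", "+", spacing * i + 10000,
                      spacing * i + 12000, ()) for i in range(n)]


def _loss(gid, is_loss):
    return LossCall(gid, 10.0 if is_loss else 1.0, 1.0, 0.1, is_loss,
                    1.0 if is_loss else 0.0)


def _de(gid, lfc, q):
    return DiffExprRecord(gid, 1.0, 1.0, lfc, q, q,
                          "up" if (q <= 0.05 and lfc > 0) else "ns")


class TestAssembleEvidence:
    def test_hand_assembled_table(self):
        genes = _genes(5)
        calls = [_loss("g0", True), _loss("g1", True), _loss("g2", False)]
        de = [_de("g0", 2.0, 0.01), _de("g3", -1.0, 0.01)]
        ev = assemble_evidence(calls, {"g0", "g4"}, de, genes, flank=5000)
        assert list(ev.index) == [f"g{i}" for i in range(5)]
        assert ev.loc["g0"].tolist() == [True, True, True, False, 2.0, 1.0]
        assert not ev.loc["g1", "is_bound"] and ev.loc["g1", "is_loss"]
        assert not ev.loc["g3", "is_up"] and ev.loc["g3", "log2fc"] == -1.0
        assert ev.loc["g2", "log2fc"] == 0.0  # missing DE -> defaults

    def test_cgi_half_open_adjacency_does_not_overlap(self):
        genes = _genes(2)
        # g0 window = [5000, 15000); CGI ending exactly at 5000 abuts only
        ev = assemble_evidence([], set(), [], genes, flank=5000,
                               cgi_intervals=[("chr1", 4000, 5000)])
        assert not ev.loc["g0", "has_cgi"]
        ev2 = assemble_evidence([], set(), [], genes, flank=5000,
                                cgi_intervals=[("chr1", 4000, 5001)])
        assert ev2.loc["g0", "has_cgi"] and not ev2.loc["g1", "has_cgi"]

    def test_unknown_gene_in_evidence_errors(self):
        genes = _genes(2)
        with pytest.raises(ValueError):
            assemble_evidence([_loss("nope", True)], set(), [], genes)
        with pytest.raises(ValueError):
            assemble_evidence([], {"nope"}, [], genes)


class TestDraftGrn:
    def _evidence(self, loss, bound, up, universe):
        rows = []
        for g in universe:
            rows.append({"gene_id": g, "is_loss": g in loss, "is_bound": g in bound,
                         "is_up": g in up, "has_cgi": False,
                         "log2fc": 2.0 if g in up else 0.0, "support": 1.0})
        return pd.DataFrame(rows).set_index("gene_id")

    def test_intersection_set_logic(self):
        uni = list("ABCDE")
        ev = self._evidence({"A", "B", "C"}, {"B", "C", "D"}, {"B", "C", "E"}, uni)
        net = draft_grn(ev)
        assert net.targets == {"B", "C"}
        assert set(net.graph.edges()) == {("Mtf2", "B"), ("Mtf2", "C")}
        assert net.graph.nodes["C"]["expression_delta"] == 2.0
        assert all(d["sign"] == "repression" for _, _, d in net.graph.edges(data=True))

    def test_empty_intersection_gives_empty_network(self):
        ev = self._evidence(set(), {"A"}, {"A"}, list("AB"))
        assert draft_grn(ev).size == 0

    def test_row_order_invariance_and_idempotence(self):
        uni = list("ABCDE")
        ev = self._evidence({"A", "B"}, {"B"}, {"B"}, uni)
        shuffled = ev.sample(frac=1.0, random_state=4)
        assert draft_grn(ev).targets == draft_grn(shuffled).targets == {"B"}
        assert draft_grn(ev).targets == draft_grn(ev).targets


class TestEnrichment:
    def test_exact_match_ranks_first(self):
        uni = {f"g{i}" for i in range(60)}
        query = {f"g{i}" for i in range(10)}
        colls = {"match": set(query), "other": {f"g{i}" for i in range(30, 45)},
                 "partial": {f"g{i}" for i in range(5, 20)}}
        table = gene_set_enrichment(query, colls, uni)
        assert table.iloc[0]["set"] == "match"

    def test_disjoint_collection_not_enriched(self):
        uni = {f"g{i}" for i in range(40)}
        query = {f"g{i}" for i in range(8)}
        colls = {"inside": {f"g{i}" for i in range(8)},
                 "outside": {f"g{i}" for i in range(20, 30)}}
        table = gene_set_enrichment(query, colls, uni).set_index("set")
        assert table.loc["inside", "pvalue"] < 1e-6
        assert table.loc["outside", "overlap"] == 0

    def test_pvalues_match_enumeration_oracle(self):
        uni = {f"g{i}" for i in range(50)}
        query = {f"g{i}" for i in range(12)}
        colls = {"a": {f"g{i}" for i in range(6, 20)},
                 "b": {f"g{i}" for i in range(12, 22)},
                 "c": {f"g{i}" for i in range(3)}}
        table = gene_set_enrichment(query, colls, uni).set_index("set")
        for name, cset in colls.items():
            a = len(query & cset)
            b = len(query - cset)
            c = len(cset - query)
            d = 50 - a - b - c
            assert table.loc[name, "pvalue"] == pytest.approx(
                fisher_two_sided_oracle(a, b, c, d), abs=1e-12)

    def test_empty_query_gives_p_one(self):
        uni = {f"g{i}" for i in range(20)}
        table = gene_set_enrichment(set(), {"s": {"g1", "g2"}}, uni)
        assert table.iloc[0]["overlap"] == 0
        assert table.iloc[0]["pvalue"] == 1.0


def test_gmt_and_network_export(tmp_path):
    gmt = tmp_path / "sets.gmt"
    gmt.write_text("wnt\tdesc\tg1\tg2\ng_other\tdesc\tg3\n")
    sets = read_gmt(gmt)
    assert sets == {"wnt": {"g1", "g2"}, "g_other": {"g3"}}

    ev = pd.DataFrame({"is_loss": [True], "is_bound": [True], "is_up": [True],
                       "has_cgi": [True], "log2fc": [1.5], "support": [1.0]},
                      index=pd.Index(["g1"], name="gene_id"))
    net = draft_grn(ev)
    write_sif(net, tmp_path / "n.sif")
    assert (tmp_path / "n.sif").read_text() == "Mtf2\trepresses\tg1\n"
    write_network_tables(net, tmp_path / "nodes.tsv", tmp_path / "edges.tsv")
    nodes = pd.read_csv(tmp_path / "nodes.tsv", sep="\t")
    assert nodes.loc[0, "expression_delta"] == 1.5
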