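"""Hypergeometric overlap test, pair calling, network assembly, the key-gene
mini-network, and set enrichment."""

from itertools import combinations

import numpy as np
import pytest

from cernanet.cerna import (
    CeRNANetworkModel,
    assemble_network,
    build_cerna_pairs,
    extract_mini_network,
    hypergeom_overlap_test,
    set_enrichment,
)
from cernanet.io import load_table1
from cernanet.targets import TargetInteraction
from tests.conftest import make_counts


def enumeration_upper_tail(k, size_a, size_b, universe):
    """Oracle: count draws of size_b from the universe with >= k hits in A."""
    a = set(range(size_a))
    hits = sum(
        1 for draw in combinations(range(universe), size_b) if len(a & set(draw)) >= k
    )
    total = sum(1 for _ in combinations(range(universe), size_b))
    return hits / total


def seed(m, t):
    return TargetInteraction(source_id=m, target_id=t, mode="seed")


class TestHypergeomOverlap:
    def test_exact_combinatorial_example(self):
        # C(3,2)C(7,2) + C(3,3)C(7,1) over C(10,4) = 70/210
        assert hypergeom_overlap_test(2, 3, 4, 10) == pytest.approx(70 / 210)

    def test_zero_overlap_is_one(self):
        assert hypergeom_overlap_test(0, 5, 5, 20) == 1.0

    def test_forced_full_overlap_is_one(self):
        assert hypergeom_overlap_test(6, 6, 6, 6) == 1.0

    def test_symmetry_in_set_sizes(self):
        for k, a, b, n in [(1, 3, 5, 12), (2, 4, 6, 15), (3, 7, 4, 9)]:
            assert hypergeom_overlap_test(k, a, b, n) == pytest.approx(
                hypergeom_overlap_test(k, b, a, n)
            )

    def test_inconsistent_arguments_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_overlap_test(4, 3, 5, 10)  # k > |A|
        with pytest.raises(ValueError):
            hypergeom_overlap_test(1, 3, 11, 10)  # draw larger than universe

    def test_enumeration_oracle_small_universe(self):
        for n in range(1, 9):
            for a in range(n + 1):
                for b in range(n + 1):
                    for k in range(min(a, b) + 1):
                        assert hypergeom_overlap_test(k, a, b, n) == pytest.approx(
                            enumeration_upper_tail(k, a, b, n), abs=1e-12
                        )


class TestBuildPairs:
    def test_zero_shared_never_tested(self):
        interactions = [seed("m1", "l1"), seed("m2", "g1")]
        pairs = build_cerna_pairs(interactions, {"l1"}, {"g1"}, {"m1", "m2"})
        assert pairs == []

    def test_positive_correlation_required(self):
        # strong overlap but anti-correlated expression -> not called
        universe = {f"m{i}" for i in range(30)}
        shared = sorted(universe)[:12]
        interactions = [seed(m, "l1") for m in shared] + [seed(m, "g1") for m in shared]
        lnc = make_counts([[1, 2, 3, 4, 5, 6]], features=["l1"], layer="FPKM")
        gene = make_counts([[6, 5, 4, 3, 2, 1]], features=["g1"], layer="FPKM")
        (pair,) = build_cerna_pairs(interactions, {"l1"}, {"g1"}, universe, lnc, gene)
        assert pair.p_value < 0.01 and pair.q_value < 0.01
        assert pair.r < 0 and not pair.called

    def test_called_with_positive_correlation(self):
        universe = {f"m{i}" for i in range(30)}
        shared = sorted(universe)[:12]
        interactions = [seed(m, "l1") for m in shared] + [seed(m, "g1") for m in shared]
        lnc = make_counts([[1, 2, 3, 4, 5, 6]], features=["l1"], layer="FPKM")
        gene = make_counts([[2, 4, 6, 8, 10, 13]], features=["g1"], layer="FPKM")
        (pair,) = build_cerna_pairs(interactions, {"l1"}, {"g1"}, universe, lnc, gene)
        assert pair.called and pair.k == 12

    def test_interactions_restricted_to_analysis_sets(self):
        interactions = [seed("m1", "l1"), seed("m1", "g1"), seed("m2", "l2"), seed("m2", "g1")]
        pairs = build_cerna_pairs(interactions, {"l1"}, {"g1"}, {"m1"})
        assert len(pairs) == 1
        assert pairs[0].lncrna_id == "l1" and pairs[0].shared == {"m1"}

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            build_cerna_pairs([], {"l"}, {"g"}, set())

    def test_tightening_thresholds_shrinks_called_set(self):
        rng = np.random.default_rng(12)
        mirnas = [f"m{i}" for i in range(20)]
        lncs = [f"l{i}" for i in range(10)]
        genes = [f"g{i}" for i in range(10)]
        interactions = []
        for m in mirnas:
            for t in lncs + genes:
                if rng.random() < 0.3:
                    interactions.append(seed(m, t))
        prev = None
        for p_thr in (0.5, 0.1, 0.01):
            pairs = build_cerna_pairs(
                interactions, lncs, genes, mirnas, p_threshold=p_thr, fdr_threshold=0.5
            )
            called = {(p.lncrna_id, p.mrna_id) for p in pairs if p.called}
            if prev is not None:
                assert called <= prev
            prev = called


class TestAssembleNetwork:
    def make_called(self):
        interactions = [
            seed("m1", "l1"), seed("m1", "g1"), seed("m2", "l1"), seed("m2", "g1"),
        ]
        pairs = build_cerna_pairs(
            interactions, {"l1"}, {"g1"}, {f"m{i}" for i in range(1, 9)},
            p_threshold=0.2, fdr_threshold=1.0,
        )
        called = [p for p in pairs if p.called]
        assert len(called) == 1 and called[0].k == 2
        return called, interactions

    def test_counts_for_one_pair_sharing_two_mirnas(self):
        called, interactions = self.make_called()
        graph, triplets = assemble_network(called, interactions)
        assert len(triplets) == 2
        assert graph.number_of_nodes() == 4  # l1, g1, m1, m2
        assert graph.number_of_edges() == 5  # 2 m->l, 2 m->g, 1 l-g

    def test_triplet_count_equals_sum_of_k(self):
        rng = np.random.default_rng(13)
        mirnas = [f"m{i}" for i in range(15)]
        lncs = [f"l{i}" for i in range(6)]
        genes = [f"g{i}" for i in range(6)]
        interactions = []
        for m in mirnas:
            for t in lncs + genes:
                if rng.random() < 0.4:
                    interactions.append(seed(m, t))
        pairs = build_cerna_pairs(
            interactions, lncs, genes, mirnas, p_threshold=1.1, fdr_threshold=2.0
        )
        called = [p for p in pairs if p.called]
        _, triplets = assemble_network(called, interactions)
        assert len(triplets) == sum(p.k for p in called)

    def test_empty_called_set_empty_network(self):
        graph, triplets = assemble_network([], [])
        assert graph.number_of_nodes() == 0 and triplets == []

    def test_unknown_interaction_integrity_error(self):
        called, interactions = self.make_called()
        with pytest.raises(ValueError, match="absent"):
            assemble_network(called, interactions[:1])

    def test_model_fit_summary(self):
        interactions = [
            seed("m1", "l1"), seed("m1", "g1"), seed("m2", "l1"), seed("m2", "g1"),
        ]
        model = CeRNANetworkModel(interactions, {"l1"}, {"g1"}, {f"m{i}" for i in range(1, 9)})
        res = model.fit(p_threshold=0.2, fdr_threshold=1.0)
        assert "called pairs: 1" in res.summary()
        assert len(res.triplets) == 2


class TestMiniNetwork:
    def test_full_fixture_reproduces_printed_summary(self):
        summary, graph = extract_mini_network(load_table1())
        assert summary.genes == 10
        assert summary.lncrnas == 37
        assert summary.mirnas == 9
        assert summary.gene_lncrna_interactions == 39

    def test_counts_match_independent_set_union(self):
        records = [r for r in load_table1() if r.mirnas and r.lncrnas]
        summary, _ = extract_mini_network(load_table1())
        assert summary.lncrnas == len(set().union(*(r.lncrnas for r in records)))
        assert summary.mirnas == len(set().union(*(r.mirnas for r in records)))

    def test_empty_records_zero_summary(self):
        summary, graph = extract_mini_network([])
        assert (summary.genes, summary.lncrnas, summary.mirnas, summary.gene_lncrna_interactions) == (0, 0, 0, 0)

    def test_small_counting_contract(self):
        from cernanet.io import Table1Record

        rec = Table1Record("X", 1.0, 0.01, ("mA",), ("l1", "l2"), "angiogenesis", "")
        summary, _ = extract_mini_network([rec])
        assert (summary.genes, summary.lncrnas, summary.mirnas, summary.gene_lncrna_interactions) == (1, 2, 1, 2)

    def test_allowlist_restricts_genes(self):
        summary, _ = extract_mini_network(load_table1(), gene_allowlist={"ACTC1"})
        assert summary.genes == 1 and summary.gene_lncrna_interactions == 4


class TestSetEnrichment:
    def test_query_equals_universe_is_certain(self):
        uni = {f"g{i}" for i in range(10)}
        df = set_enrichment(uni, {"term": list(uni)}, uni)
        assert df["p_value"].iloc[0] == pytest.approx(1.0)

    def test_same_arithmetic_as_overlap_example(self):
        uni = [f"g{i}" for i in range(10)]
        df = set_enrichment(uni[:4], {"t": uni[:2] + uni[8:9]}, uni)
        # overlap 2 of a 3-gene term, query 4, universe 10 -> 70/210
        assert df["overlap"].iloc[0] == 2
        assert df["p_value"].iloc[0] == pytest.approx(70 / 210)

    def test_empty_overlap_is_one(self):
        uni = [f"g{i}" for i in range(10)]
        df = set_enrichment(uni[:2], {"t": uni[5:8]}, uni)
        assert df["p_value"].iloc[0] == pytest.approx(1.0)

    def test_gene_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            set_enrichment({"g1"}, {"t": ["zzz"]}, {"g1", "g2"})
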