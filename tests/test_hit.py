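import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colitiskit.hit import (
    CompoundRecord,
    DiseaseGeneSource,
    build_hit_network,
    collate_disease_genes,
    combined_target_coverage,
    filter_adme,
    herb_target_share,
    intersect_targets,
    normalize_gene_symbols,
)


def rec(herb="H1", cid="C1", ob=30.0, dl=0.5, targets=("TNF",)):
    return CompoundRecord(herb, cid, f"name-{cid}", ob, dl, set(targets))


class TestAdmeFilter:
    def test_boundary_is_inclusive(self):
        assert filter_adme([rec(ob=20.0, dl=0.18)]) == [rec(ob=20.0, dl=0.18)]

    def test_failing_one_criterion_drops(self):
        assert filter_adme([rec(ob=19.9, dl=0.90)]) == []
        assert filter_adme([rec(ob=45.0, dl=0.17)]) == []

    def test_empty_input(self):
        assert filter_adme([]) == []

    def test_order_preserved_and_idempotent(self):
        records = [rec(cid=f"C{i}", ob=10 + 5 * i) for i in range(6)]
        kept = filter_adme(records)
        assert kept == [r for r in records if r.ob >= 20]
        assert filter_adme(kept) == kept

    def test_negative_values_rejected_naming_record(self):
        with pytest.raises(ValueError, match="C9"):
            CompoundRecord("H1", "C9", "x", -1.0, 0.5, set())


class TestGeneSymbols:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            (["Tnf", "TNF", " il6 "], {"TNF", "IL6"}),
            ([], set()),
            (["PTGS2"], {"PTGS2"}),
            (["", "  ", "a"], {"A"}),
        ],
    )
    def test_normalization(self, raw, expected):
        assert normalize_gene_symbols(raw) == expected

    @given(st.lists(st.text(max_size=8)))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, raw):
        once = normalize_gene_symbols(raw)
        assert normalize_gene_symbols(once) == once


class TestCollate:
    def test_two_source_regions(self):
        union, regions = collate_disease_genes(
            [DiseaseGeneSource("A", {"g1", "g2"}), DiseaseGeneSource("B", {"g2", "g3"})]
        )
        assert union == {"g1", "g2", "g3"}
        assert regions[frozenset({"A"})] == 1
        assert regions[frozenset({"B"})] == 1
        assert regions[frozenset({"A", "B"})] == 1

    def test_single_source(self):
        union, regions = collate_disease_genes([DiseaseGeneSource("A", {"g1"})])
        assert union == {"g1"} and regions == {frozenset({"A"}): 1}

    def test_duplicate_source_name_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            collate_disease_genes(
                [DiseaseGeneSource("A", {"x"}), DiseaseGeneSource("A", {"y"})]
            )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_region_counts_sum_to_union(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        sources = [
            DiseaseGeneSource(
                f"S{i}", {f"g{int(x)}" for x in rng.integers(0, 120, size=50)}
            )
            for i in range(5)
        ]
        union, regions = collate_disease_genes(sources)
        assert sum(regions.values()) == len(union)
        # brute-force membership tabulation
        for g in union:
            mem = frozenset(s.source_name for s in sources if g in s.genes)
            assert regions[mem] >= 1


class TestIntersect:
    def test_basic_identity_disjoint(self):
        assert intersect_targets({"a", "b", "c"}, {"b", "c", "d"}) == {"b", "c"}
        assert intersect_targets({"a"}, {"b"}) == set()
        x = {"p", "q"}
        assert intersect_targets(x, x) == x


class TestHitNetwork:
    def test_single_compound_two_targets_one_kept(self):
        net = build_hit_network([rec(targets={"T1", "T2"})], {"T1"})
        layers = nx.get_node_attributes(net, "layer")
        assert sorted(layers.values()) == ["compound", "herb", "target"]
        assert net.number_of_edges() == 2

    def test_compound_without_kept_targets_pruned(self):
        net = build_hit_network([rec(targets={"T9"})], {"T1"})
        assert net.number_of_nodes() == 0

    def test_shared_compound_has_two_herb_parents(self):
        records = [
            rec(herb="H1", cid="Cs", targets={"T1"}),
            rec(herb="H2", cid="Cs", targets={"T1"}),
        ]
        net = build_hit_network(records, {"T1"})
        herbs = {n for n in net.neighbors("Cs")
                 if net.nodes[n]["layer"] == "herb"}
        assert herbs == {"H1", "H2"}

    def test_tripartite_no_within_layer_edges(self):
        records = [
            rec(herb="H1", cid="C1", targets={"T1", "T2"}),
            rec(herb="H2", cid="C2", targets={"T2", "T3"}),
        ]
        net = build_hit_network(records, {"T1", "T2", "T3"})
        order = {"herb": 0, "compound": 1, "target": 2}
        for a, b in net.edges:
            la, lb = net.nodes[a]["layer"], net.nodes[b]["layer"]
            assert abs(order[la] - order[lb]) == 1

    def test_empty_network_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            build_hit_network([rec(targets={"T9"})], {"T1"})


class TestHerbShare:
    def test_share_and_combined_coverage(self):
        records = [
            rec(herb="H1", cid="C1", targets={"a", "b"}),
            rec(herb="H2", cid="C2", targets={"b", "c"}),
        ]
        net = build_hit_network(records, {"a", "b", "c"})
        share = herb_target_share(net)
        assert share["H1"] == (2, pytest.approx(2 / 3))
        assert share["H2"] == (2, pytest.approx(2 / 3))
        assert combined_target_coverage(net, ["H1", "H2"]) == 1.0

    def test_single_herb_full_coverage(self):
        net = build_hit_network([rec(targets={"a", "b"})], {"a", "b"})
        assert herb_target_share(net)["H1"] == (2, 1.0)

    def test_all_herbs_cover_everything(self):
        records = [rec(herb=f"H{i}", cid=f"C{i}",
                       targets={f"T{i}", f"T{i + 1}"}) for i in range(4)]
        net = build_hit_network(records, {f"T{i}" for i in range(6)})
        herbs = [h for h, d in net.nodes(data=True) if d["layer"] == "herb"]
        assert combined_target_coverage(net, herbs) == 1.0
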