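"""Ontology parsing, closure, propagation, ordering and split behaviour."""

import numpy as np
import pytest

from hiergo.ontology import (
    AnnotationTable,
    OntologyError,
    ancestor_index,
    make_zero_shot_split,
    parse_obo,
    propagate_true_path,
    read_annotations,
    subsumption_ranking_eval,
    topological_order,
)
from hiergo.text_embedding import TermEmbeddingMatrix

from conftest import make_obo, random_dag_obo, term_stanza


class TestParseObo:
    def test_three_stanza_chain(self, chain_graph):
        assert len(chain_graph.active_terms()) == 3
        assert chain_graph.dag.number_of_edges() == 2
        assert chain_graph.roots == {"MF": "T:0"}

    def test_obsolete_term_kept_but_unconnected(self):
        text = make_obo(
            [
                term_stanza("T:0", "root"),
                term_stanza("T:1", "gone", parents=["T:0"], obsolete=True),
            ]
        )
        graph = parse_obo(text)
        assert graph.terms["T:1"].obsolete
        assert "T:1" not in graph.dag.nodes
        assert "T:1" not in ancestor_index(graph).ancestors

    def test_cycle_raises_structural_error(self):
        text = make_obo(
            [
                term_stanza("T:a", "a", parents=["T:b"]),
                term_stanza("T:b", "b", parents=["T:a"]),
            ]
        )
        with pytest.raises(OntologyError, match="cycle"):
            parse_obo(text)

    def test_unknown_parent_raises(self):
        text = make_obo([term_stanza("T:1", "orphan", parents=["T:404"])])
        with pytest.raises(OntologyError, match="never declared"):
            parse_obo(text)

    def test_relation_filter_drops_regulates(self):
        text = make_obo(
            [
                term_stanza("T:0", "root"),
                "\n".join(
                    [
                        "[Term]",
                        "id: T:1",
                        "name: regulated",
                        "namespace: molecular_function",
                        "is_a: T:0",
                        "relationship: regulates T:0",
                    ]
                ),
            ]
        )
        graph = parse_obo(text)
        assert graph.dag.number_of_edges() == 1
        wide = parse_obo(text, {"is_a", "part_of", "regulates"})
        assert wide.dag.number_of_edges() == 1  # parallel edge collapses in the DAG

    def test_term_reaching_two_roots_rejected(self):
        text = make_obo(
            [
                term_stanza("T:0", "mf root", namespace="molecular_function"),
                term_stanza("T:9", "bp root", namespace="biological_process"),
                term_stanza("T:1", "confused", parents=["T:0", "T:9"]),
            ]
        )
        with pytest.raises(OntologyError, match="aspect roots"):
            parse_obo(text)


class TestAncestorIndex:
    def test_chain_exclusive_and_inclusive(self, chain_graph):
        ex = ancestor_index(chain_graph, include_self=False)
        assert ex["T:2"] == {"T:1", "T:0"}
        assert ex["T:0"] == frozenset()
        inc = ancestor_index(chain_graph, include_self=True)
        assert inc["T:2"] == {"T:2", "T:1", "T:0"}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dfs_reachability_oracle(self, seed):
        import networkx as nx

        rng = np.random.default_rng(seed)
        graph = parse_obo(random_dag_obo(rng, n_terms=50))
        index = ancestor_index(graph)
        for node in graph.dag.nodes:
            # oracle: brute-force DFS reachability along child→parent edges
            reachable = set()
            stack = [node]
            while stack:
                for nxt in graph.dag.successors(stack.pop()):
                    if nxt not in reachable:
                        reachable.add(nxt)
                        stack.append(nxt)
            assert index[node] == reachable


class TestPropagation:
    def test_chain_closure(self, chain_graph):
        table = AnnotationTable.from_pairs([("p", "T:2")])
        out = propagate_true_path(table, ancestor_index(chain_graph, include_self=True))
        assert out.terms_of("p") == {"T:2", "T:1", "T:0"}
        assert out.propagated

    def test_idempotent_and_monotone(self, diamond_graph):
        index = ancestor_index(diamond_graph, include_self=True)
        table = AnnotationTable.from_pairs([("p", "T:c"), ("q", "T:a")])
        once = propagate_true_path(table, index)
        twice = propagate_true_path(once, index)
        assert once.records.equals(twice.records)
        # monotone: adding a record never removes outputs
        bigger = AnnotationTable.from_pairs(
            [("p", "T:c"), ("q", "T:a"), ("q", "T:b")]
        )
        out_b = propagate_true_path(bigger, index)
        assert set(map(tuple, once.records.values)) <= set(map(tuple, out_b.records.values))

    def test_unknown_term_rejected(self, chain_graph):
        table = AnnotationTable.from_pairs([("p", "T:404")])
        with pytest.raises(ValueError, match="T:404"):
            propagate_true_path(table, ancestor_index(chain_graph))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_union_closure_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        graph = parse_obo(random_dag_obo(rng, n_terms=40))
        index = ancestor_index(graph, include_self=True)
        terms = graph.active_terms()
        pairs = [
            (f"p{i}", terms[rng.integers(len(terms))])
            for i in range(20)
        ]
        out = propagate_true_path(AnnotationTable.from_pairs(pairs), index)
        for protein in {p for p, _ in pairs}:
            expected = set()
            for p, t in pairs:
                if p == protein:
                    expected |= set(index[t])
            assert out.terms_of(protein) == expected


class TestTopologicalOrder:
    def test_diamond_hierarchical(self, diamond_graph):
        order = topological_order(diamond_graph, "MF", "hierarchical")
        assert list(order.term_ids) == ["T:0", "T:a", "T:b", "T:c"]

    def test_go_id_mode_plain_sort(self, diamond_graph):
        order = topological_order(diamond_graph, "MF", "go_id")
        assert list(order.term_ids) == sorted(diamond_graph.aspect_terms("MF"))

    @pytest.mark.parametrize("seed", range(20))
    def test_hierarchical_is_linear_extension_and_deterministic(self, seed):
        rng = np.random.default_rng(200 + seed)
        graph = parse_obo(random_dag_obo(rng, n_terms=60))
        aspect = next(iter(graph.roots))
        order = topological_order(graph, aspect, "hierarchical")
        rank = order.rank
        for child, parent in graph.dag.edges:
            assert rank[parent] < rank[child]
        again = topological_order(graph, aspect, "hierarchical")
        assert order.term_ids == again.term_ids


class TestZeroShotSplit:
    def test_protein_with_only_held_out_leaf_becomes_empty(self, chain_graph):
        index = ancestor_index(chain_graph, include_self=True)
        table = AnnotationTable.from_pairs([("p", "T:2")])
        train, held = make_zero_shot_split(table, {"T:2"}, index)
        assert train.terms_of("p") == set()
        assert held == {"T:2"}

    def test_unrelated_annotation_survives(self, diamond_graph):
        index = ancestor_index(diamond_graph, include_self=True)
        table = AnnotationTable.from_pairs([("p", "T:c"), ("p", "T:a")])
        train, _ = make_zero_shot_split(table, {"T:c"}, index)
        assert train.terms_of("p") == {"T:a", "T:0"}

    def test_empty_held_out_equals_plain_propagation(self, diamond_graph):
        index = ancestor_index(diamond_graph, include_self=True)
        table = AnnotationTable.from_pairs([("p", "T:c")])
        train, _ = make_zero_shot_split(table, set(), index)
        assert train.records.equals(propagate_true_path(table, index).records)

    def test_missing_held_out_term_rejected(self, chain_graph):
        index = ancestor_index(chain_graph, include_self=True)
        with pytest.raises(ValueError, match="T:404"):
            make_zero_shot_split(AnnotationTable.from_pairs([("p", "T:2")]), {"T:404"}, index)


class TestAnnotationIO:
    def test_simple_tsv_roundtrip(self, tmp_path):
        import io

        table = read_annotations(io.StringIO("protein_id\tterm_id\np1\tT:1\np2\tT:2\n"))
        assert len(table) == 2

    def test_gaf_by_column_position(self):
        import io

        gaf = "!gaf-version: 2.2\nUniProt\tP12345\tGENE\t\tGO:0001\tPMID:1\tIEA\t\tF\n"
        table = read_annotations(io.StringIO(gaf))
        assert table.records.iloc[0].tolist() == ["P12345", "GO:0001"]


class TestSubsumptionRanking:
    def test_two_term_graph_mrr_one(self):
        text = make_obo([term_stanza("T:0", "root"), term_stanza("T:1", "c", parents=["T:0"])])
        graph = parse_obo(text)
        emb = TermEmbeddingMatrix(["T:0", "T:1"], np.array([[1.0, 0.0], [0.8, 0.2]]))
        report = subsumption_ranking_eval(emb, graph)
        assert report.mrr == 1.0
        assert report.n_children == 1

    def test_parent_mean_embeddings_give_high_mrr(self):
        rng = np.random.default_rng(0)
        graph = parse_obo(random_dag_obo(rng, n_terms=30))
        terms = graph.active_terms()
        dim = 32
        vecs = {t: rng.standard_normal(dim) for t in terms}
        # children sit at the mean of their parents plus tiny noise
        for t in terms:
            parents = graph.parents(t)
            if parents:
                vecs[t] = np.mean([vecs[p] for p in sorted(parents)], axis=0)
                vecs[t] = vecs[t] + 1e-3 * rng.standard_normal(dim)
        emb = TermEmbeddingMatrix(terms, np.stack([vecs[t] for t in terms]))
        report = subsumption_ranking_eval(emb, graph)
        assert report.mrr > 0.5
        assert report.auc > 0.8

    def test_orthogonal_embeddings_near_chance(self):
        rng = np.random.default_rng(1)
        n = 100
        stanzas = [term_stanza("T:000", "root")]
        for i in range(1, n):
            stanzas.append(term_stanza(f"T:{i:03d}", f"t{i}", parents=["T:000"]))
        graph = parse_obo(make_obo(stanzas))
        emb = TermEmbeddingMatrix(graph.active_terms(), rng.standard_normal((n, 64)))
        report = subsumption_ranking_eval(emb, graph)
        # hits@1 for the single true parent among 99 candidates ≈ 1/99
        assert report.hits_at_1 < 0.08
        assert 0.35 < report.auc < 0.65

    def test_missing_row_rejected(self, chain_graph):
        emb = TermEmbeddingMatrix(["T:0", "T:1"], np.eye(2))
        with pytest.raises(ValueError, match="without embedding"):
            subsumption_ranking_eval(emb, chain_graph)
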