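"""Graph stage: ancestors, spin-glass partitioning, HITS, collapse, export."""

import networkx as nx
import numpy as np
import pytest
from helpers_oracles import (
    authority_eig,
    exhaustive_min_energy,
    partitions_equivalent,
    potts_energy,
)

from acidscreen.gograph import (
    AnnealSchedule,
    ancestors,
    authority_scores,
    build_subgraph,
    collapse,
    export_dot,
    export_graphml,
    hamiltonian,
    select_representatives,
    spinglass_partition,
)

FAST = AnnealSchedule(t_start=1.0, t_stop=0.05, cooling=0.95)


def two_clique_bridge():
    g = nx.relabel_nodes(
        nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4)),
        {i: f"n{i}" for i in range(8)},
    )
    g.add_edge("n3", "n4")
    return g


class TestAncestors:
    def test_root_has_none(self, diamond_ontology):
        assert ancestors("R", diamond_ontology) == frozenset()

    def test_chain(self, diamond_ontology):
        assert ancestors("D", diamond_ontology) == {"C", "A", "B", "R"}

    def test_diamond_deduplicates(self, diamond_ontology):
        assert ancestors("C", diamond_ontology) == {"A", "B", "R"}

    def test_unknown_term(self, diamond_ontology):
        with pytest.raises(KeyError):
            ancestors("nope", diamond_ontology)


class TestBuildSubgraph:
    def test_single_leaf_gives_ancestor_path(self, diamond_ontology):
        sub = build_subgraph({"D"}, diamond_ontology)
        assert set(sub.nodes) == {"D", "C", "A", "B", "R"}
        assert sub.nodes["D"]["significant"] and not sub.nodes["C"]["significant"]

    def test_sibling_union_deduplicated(self, diamond_ontology):
        sub = build_subgraph({"C", "E"}, diamond_ontology)
        assert set(sub.nodes) == {"C", "E", "A", "B", "R"}
        assert sub.number_of_edges() == 5  # induced ontology edges only

    def test_all_terms_reproduce_full_ontology(self, diamond_ontology):
        sub = build_subgraph(set(diamond_ontology.nodes), diamond_ontology)
        assert set(sub.edges) == set(diamond_ontology.edges)

    def test_empty_or_unknown_input(self, diamond_ontology):
        with pytest.raises(ValueError):
            build_subgraph(set(), diamond_ontology)
        with pytest.raises(KeyError):
            build_subgraph({"nope"}, diamond_ontology)


class TestHamiltonian:
    def test_singleton_partition_is_zero(self):
        g = nx.path_graph(5)
        assert hamiltonian(g, {n: n for n in g.nodes}) == 0.0

    def test_triangle_all_same(self):
        g = nx.complete_graph(3)
        assert hamiltonian(g, {n: 0 for n in g.nodes}) == pytest.approx(-1.0)

    def test_complete_graph_prefers_one_community(self):
        g = nx.complete_graph(5)
        h_same = hamiltonian(g, {n: 0 for n in g.nodes})
        _, best = exhaustive_min_energy(g)
        assert partitions_equivalent({n: 0 for n in g.nodes}, best)
        for split in ([0, 0, 0, 1, 1], [0, 1, 2, 3, 4], [0, 0, 1, 1, 2]):
            assert h_same <= hamiltonian(g, dict(zip(g.nodes, split))) + 1e-12

    def test_matches_independent_energy_oracle(self):
        g = two_clique_bridge()
        part = {n: (0 if n in {"n0", "n1", "n2", "n3"} else 1) for n in g.nodes}
        groups = [{n for n, c in part.items() if c == lab} for lab in (0, 1)]
        assert hamiltonian(g, part) == pytest.approx(potts_energy(g, groups))

    def test_unlabeled_node_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(KeyError):
            hamiltonian(g, {0: 0, 1: 0})


class TestSpinglass:
    def test_two_cliques_split_at_the_bridge(self):
        g = two_clique_bridge()
        part = spinglass_partition(g, seed=1, schedule=FAST)
        _, best = exhaustive_min_energy(g)
        assert partitions_equivalent(part, best)
        assert partitions_equivalent(
            part, [{"n0", "n1", "n2", "n3"}, {"n4", "n5", "n6", "n7"}]
        )

    def test_single_clique_is_one_community(self):
        part = spinglass_partition(nx.complete_graph(6), seed=0, schedule=FAST)
        assert len(set(part.values())) == 1

    def test_max_spins_respected(self):
        g = nx.path_graph(30)
        part = spinglass_partition(g, max_spins=3, seed=0, schedule=FAST)
        assert len(set(part.values())) <= 3

    def test_edgeless_graph_warns_and_isolates(self):
        g = nx.empty_graph(4)
        with pytest.warns(UserWarning, match="no edges"):
            part = spinglass_partition(g, seed=0)
        assert len(set(part.values())) == 4

    def test_disconnected_components_get_distinct_labels(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        part = spinglass_partition(g, seed=2, schedule=FAST)
        labels_a = {part[n] for n in range(4)}
        labels_b = {part[n] for n in range(4, 8)}
        assert labels_a.isdisjoint(labels_b)

    def test_seed_determinism(self):
        g = nx.gnp_random_graph(12, 0.3, seed=5)
        p1 = spinglass_partition(g, seed=9, schedule=FAST)
        p2 = spinglass_partition(g, seed=9, schedule=FAST)
        assert p1 == p2

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            spinglass_partition(nx.Graph())


class TestAuthority:
    def test_star_closed_form(self):
        g = nx.DiGraph([(f"leaf{i}", "center") for i in range(5)])
        scores = authority_scores(g)
        assert scores["center"] == pytest.approx(1.0)
        assert all(scores[f"leaf{i}"] == pytest.approx(0.0) for i in range(5))

    def test_edgeless_graph_scores_zero(self):
        g = nx.DiGraph()
        g.add_nodes_from("abc")
        assert authority_scores(g) == {"a": 0.0, "b": 0.0, "c": 0.0}

    def test_matches_dense_eigen_oracle(self):
        for seed in range(10):
            g = nx.gnp_random_graph(8, 0.35, seed=seed, directed=True)
            if g.number_of_edges() == 0:
                continue
            expected, gap = authority_eig(g)
            if gap < 1e-6:
                continue
            scores = authority_scores(g)
            assert all(abs(scores[n] - expected[n]) <= 1e-8 for n in g.nodes)

    def test_nonnegative_unit_norm_and_order_invariant(self):
        g = nx.gnp_random_graph(9, 0.4, seed=3, directed=True)
        scores = authority_scores(g)
        vec = np.array([scores[n] for n in sorted(g.nodes)])
        assert (vec >= 0).all()
        assert np.linalg.norm(vec) == pytest.approx(1.0)
        shuffled = nx.DiGraph()
        shuffled.add_nodes_from(reversed(list(g.nodes)))
        shuffled.add_edges_from(reversed(list(g.edges)))
        assert authority_scores(shuffled) == scores


class TestRepresentatives:
    def test_unique_maximum_independent_of_seed(self):
        part = {"a": 1, "b": 1, "c": 1}
        scores = {"a": 0.1, "b": 0.9, "c": 0.5}
        assert all(
            select_representatives(part, scores, seed=s) == {1: "b"} for s in range(20)
        )

    def test_exact_tie_split_roughly_evenly(self):
        part = {"a": 1, "b": 1}
        scores = {"a": 0.5, "b": 0.5}
        picks = [select_representatives(part, scores, seed=s)[1] for s in range(1000)]
        frac_a = picks.count("a") / 1000
        assert 0.44 <= frac_a <= 0.56  # binomial 4-sigma band around 0.5

    def test_tie_break_reproducible_and_stream_isolated(self):
        part = {"a": 1, "b": 1, "c": 2, "d": 2}
        scores = {"a": 0.5, "b": 0.5, "c": 0.2, "d": 0.2}
        r1 = select_representatives(part, scores, seed=33)
        r2 = select_representatives(part, scores, seed=33)
        assert r1 == r2
        # dropping community 2 does not change community 1's choice
        r3 = select_representatives({"a": 1, "b": 1}, {"a": 0.5, "b": 0.5}, seed=33)
        assert r3[1] == r1[1]

    def test_missing_scores_rejected(self):
        with pytest.raises(KeyError):
            select_representatives({"a": 1}, {}, seed=0)


def _toy_partitioned_graph(diamond_ontology):
    sub = build_subgraph({"D", "E"}, diamond_ontology)
    partition = {"R": 1, "A": 1, "B": 2, "C": 1, "D": 1, "E": 2}
    reps = {1: "A", 2: "B"}
    return sub, partition, reps


class TestCollapse:
    def test_two_communities_with_cross_edges(self, diamond_ontology):
        sub, partition, reps = _toy_partitioned_graph(diamond_ontology)
        out = collapse(sub, partition, reps, {"D", "E"})
        assert len(out.community_nodes) == 2
        assert sum(out.member_counts.values()) == sub.number_of_nodes()
        # cross edges C->B and B->R collapse to a mutual pair, deduplicated
        inter = [
            (u, v) for u, v, d in out.graph.edges(data=True) if d["kind"] == "inter_community"
        ]
        assert set(inter) == {("community:1", "community:2"), ("community:2", "community:1")}

    def test_membership_edges_one_per_significant_term(self, diamond_ontology):
        sub, partition, reps = _toy_partitioned_graph(diamond_ontology)
        out = collapse(sub, partition, reps, {"D", "E"})
        for term, community in (("D", 1), ("E", 2)):
            edges = [
                (u, v) for u, v, d in out.graph.edges(data=True)
                if d["kind"] == "membership" and u == term
            ]
            assert edges == [(term, f"community:{community}")]
        assert not list(nx.selfloop_edges(out.graph))

    def test_single_community(self, diamond_ontology):
        sub = build_subgraph({"D"}, diamond_ontology)
        partition = {n: 1 for n in sub.nodes}
        out = collapse(sub, partition, {1: "R"}, {"D"})
        assert len(out.community_nodes) == 1
        assert out.graph.number_of_edges() == 1  # the single membership edge

    def test_rep_ancestry_mode(self, diamond_ontology):
        sub, partition, reps = _toy_partitioned_graph(diamond_ontology)
        out = collapse(
            sub, partition, reps, {"D"}, edge_mode="rep-ancestry", ontology=diamond_ontology
        )
        inter = [
            (u, v) for u, v, d in out.graph.edges(data=True) if d["kind"] == "inter_community"
        ]
        # A and B are siblings, neither ancestor of the other: no edges
        assert inter == []

    def test_foreign_representative_rejected(self, diamond_ontology):
        sub, partition, reps = _toy_partitioned_graph(diamond_ontology)
        with pytest.raises(ValueError):
            collapse(sub, partition, {1: "B", 2: "B"}, {"D"})

    def test_unknown_edge_mode(self, diamond_ontology):
        sub, partition, reps = _toy_partitioned_graph(diamond_ontology)
        with pytest.raises(ValueError):
            collapse(sub, partition, reps, {"D"}, edge_mode="bogus")


class TestExport:
    def test_graphml_round_trip(self, diamond_ontology, tmp_path):
        sub, partition, reps = _toy_partitioned_graph(diamond_ontology)
        out = collapse(sub, partition, reps, {"D", "E"})
        path = tmp_path / "g.graphml"
        export_graphml(out, path)
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == out.graph.number_of_nodes()
        assert back.number_of_edges() == out.graph.number_of_edges()
        assert back.nodes["community:1"]["kind"] == "community"
        assert back.nodes["community:1"]["member_count"] == 4

    def test_dot_lists_community_nodes(self, diamond_ontology, tmp_path):
        sub, partition, reps = _toy_partitioned_graph(diamond_ontology)
        out = collapse(sub, partition, reps, {"D", "E"})
        path = tmp_path / "g.dot"
        export_dot(out, path)
        text = path.read_text()
        assert text.count("kind=community") == 2
        assert "digraph" in text
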