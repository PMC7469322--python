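"""SIP probabilities, influence aggregation, greedy selection and oracles."""

import math
import random

import networkx as nx
import pytest

from sipnet import (
    InfluenceConfig,
    brute_force_seeds,
    brute_force_sip,
    node_influence,
    query_influencers,
    select_seeds_greedy,
    set_influence,
    sip,
    sip_from,
    suite_relevance,
)
from sipnet.cooccurrence import CoocGraph
from sipnet.errors import NodeNotFoundError, OracleCapError, ValidationError
from sipnet.synthetic import GraphSpec, generate_graph


def make_graph(edges, colors=None):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    for n in g.nodes:
        g.nodes[n]["color"] = (colors or {}).get(n, "gene")
    cg = CoocGraph(g)
    cg.validate()
    return cg


@pytest.fixture
def star():
    return make_graph([("hub", "l1", 0.5), ("hub", "l2", 0.5), ("hub", "l3", 0.5)])


class TestSip:
    def test_single_edge(self):
        g = make_graph([("a", "b", 0.75)])
        assert sip(g, "a", "b") == 0.75

    def test_chain_product(self):
        g = make_graph([("a", "b", 0.75), ("b", "c", 0.5)])
        assert sip(g, "a", "c") == 0.375

    def test_two_hop_beats_weak_direct_edge(self):
        g = make_graph([("a", "c", 0.25), ("a", "b", 0.75), ("b", "c", 0.5)])
        assert sip(g, "a", "c") == 0.375

    def test_self_sip_is_one_and_unreachable_zero(self):
        g = make_graph([("a", "b", 0.5)])
        g.graph.add_node("lonely", color="gene")
        assert sip(g, "a", "a") == 1.0
        assert sip(g, "a", "lonely") == 0.0

    def test_symmetric_on_undirected_graph(self):
        g = make_graph([("a", "b", 0.75), ("b", "c", 0.5), ("a", "c", 0.25)])
        for u in "abc":
            for v in "abc":
                assert sip(g, u, v) == sip(g, v, u)

    def test_missing_node_raises(self, star):
        with pytest.raises(NodeNotFoundError):
            sip(star, "hub", "ghost")

    def test_sip_from_star(self, star):
        probs = sip_from(star, "hub")
        assert probs["hub"] == 1.0
        assert all(probs[l] == 0.5 for l in ("l1", "l2", "l3"))

    def test_sip_from_isolated_source(self):
        g = make_graph([("a", "b", 0.5)])
        g.graph.add_node("iso", color="gene")
        assert sip_from(g, "iso") == {"iso": 1.0}

    def test_sip_from_matches_pairwise_oracle_on_random_graph(self):
        g = generate_graph(GraphSpec(num_nodes=8, num_edges=13, random_seed=42))
        for s in g.nodes:
            fast = sip_from(g, s)
            for d in g.nodes:
                assert fast.get(d, 0.0) == pytest.approx(
                    brute_force_sip(g, s, d), abs=1e-12)

    def test_adding_an_edge_never_decreases_sip(self):
        rng = random.Random(9)
        for trial in range(25):
            g = generate_graph(GraphSpec(num_nodes=7, num_edges=8,
                                         random_seed=trial))
            nodes = sorted(g.graph.nodes)
            before = {(u, v): sip_from(g, u).get(v, 0.0)
                      for u in nodes for v in nodes}
            non_edges = [(u, v) for i, u in enumerate(nodes)
                         for v in nodes[i + 1:] if not g.graph.has_edge(u, v)]
            if not non_edges:
                continue
            u, v = rng.choice(non_edges)
            g.graph.add_edge(u, v, weight=rng.choice([0.25, 0.5, 0.75, 1.0]))
            for s in nodes:
                after = sip_from(g, s)
                for d in nodes:
                    assert after.get(d, 0.0) >= before[(s, d)] - 1e-12


class TestInfluence:
    def test_star_center_influence(self, star):
        assert node_influence(star, "hub") == pytest.approx(1.5)

    def test_star_leaf_influence_goes_through_center(self, star):
        assert node_influence(star, "l1") == pytest.approx(0.5 + 0.25 + 0.25)

    def test_singleton_graph_has_zero_influence(self):
        g = CoocGraph(nx.Graph())
        g.graph.add_node("only", color="gene")
        assert node_influence(g, "only") == 0.0

    def test_noisy_or_combination(self):
        g = make_graph([("a", "v", 0.5), ("b", "v", 0.5)])
        cfg = InfluenceConfig(aggregator="noisy_or")
        # target v gets 1 - (1-.5)(1-.5) = .75; a and b also reach each other
        # via v (sip .25) but are seeds, hence excluded as targets
        assert set_influence(g, {"a", "b"}, cfg) == pytest.approx(0.75)

    def test_max_combination(self):
        g = make_graph([("a", "v", 0.5), ("b", "v", 0.5)])
        cfg = InfluenceConfig(aggregator="max")
        assert set_influence(g, {"a", "b"}, cfg) == pytest.approx(0.5)

    def test_singleton_set_equals_node_influence(self, star):
        cfg = InfluenceConfig()
        for n in star.nodes:
            assert set_influence(star, {n}, cfg) == pytest.approx(
                node_influence(star, n, cfg))

    def test_empty_seed_set_rejected(self, star):
        with pytest.raises(ValidationError):
            set_influence(star, set())

    def test_target_color_restricts_targets(self):
        g = make_graph([("g1", "d1", 0.5), ("g1", "g2", 0.75)],
                       colors={"g1": "gene", "g2": "gene", "d1": "disease"})
        cfg = InfluenceConfig(target_color="disease")
        assert node_influence(g, "g1", cfg) == pytest.approx(0.5)


class TestGreedySelection:
    def test_star_single_seed_is_center(self, star):
        res = select_seeds_greedy(star, InfluenceConfig(num_seeds=1))
        assert res.seeds == ["hub"]
        assert res.final_influence == pytest.approx(1.5)

    def test_two_components_get_one_seed_each(self):
        g = make_graph([("a1", "a2", 1.0), ("a2", "a3", 1.0), ("a1", "a3", 1.0),
                        ("b1", "b2", 0.5), ("b2", "b3", 0.5), ("b1", "b3", 0.5)])
        res = select_seeds_greedy(g, InfluenceConfig(num_seeds=2))
        components = {s[0] for s in res.seeds}
        assert components == {"a", "b"}
        best_set, best_val = brute_force_seeds(g, InfluenceConfig(num_seeds=2))
        assert res.final_influence == pytest.approx(best_val)

    def test_all_nodes_as_seeds_leaves_no_targets(self, star):
        res = select_seeds_greedy(star, InfluenceConfig(num_seeds=4))
        assert sorted(res.seeds) == ["hub", "l1", "l2", "l3"]
        assert res.final_influence == 0.0

    def test_first_seed_is_argmax_of_node_influence(self):
        for seed in range(10):
            g = generate_graph(GraphSpec(num_nodes=7, num_edges=10,
                                         random_seed=seed))
            res = select_seeds_greedy(g, InfluenceConfig(num_seeds=2))
            best = max(sorted(g.nodes),
                       key=lambda n: (node_influence(g, n), ))
            assert node_influence(g, res.seeds[0]) == pytest.approx(
                node_influence(g, best))

    def test_infeasible_seed_count_rejected(self, star):
        with pytest.raises(ValidationError):
            select_seeds_greedy(star, InfluenceConfig(num_seeds=5))

    def test_deterministic_across_runs(self):
        g = generate_graph(GraphSpec(num_nodes=12, num_edges=25, random_seed=3))
        r1 = select_seeds_greedy(g, InfluenceConfig(num_seeds=3))
        r2 = select_seeds_greedy(g, InfluenceConfig(num_seeds=3))
        assert r1.seeds == r2.seeds
        assert r1.influence_trace == r2.influence_trace

    def test_greedy_matches_brute_force_at_s1(self):
        for seed in range(10):
            g = generate_graph(GraphSpec(num_nodes=6, num_edges=8,
                                         random_seed=seed + 50))
            res = select_seeds_greedy(g, InfluenceConfig(num_seeds=1))
            best_set, best_val = brute_force_seeds(g, InfluenceConfig(num_seeds=1))
            assert res.seeds == best_set
            assert res.final_influence == pytest.approx(best_val)


class TestQueryInfluencers:
    def test_direct_strong_edge_beats_weak_one(self):
        g = make_graph([("g1", "d1", 1.0), ("g2", "d1", 0.25)],
                       colors={"g1": "gene", "g2": "gene", "d1": "disease"})
        res = query_influencers(g, {"d1"}, k=1, source_color="gene")
        assert res.seeds == ["g1"]
        assert res.final_influence == pytest.approx(1.0)

    def test_unreachable_targets_fall_back_to_tie_break(self):
        g = make_graph([("g1", "g2", 0.5)],
                       colors={"g1": "gene", "g2": "gene"})
        g.graph.add_node("d1", color="disease")
        res = query_influencers(g, {"d1"}, k=2, source_color="gene")
        assert res.seeds == ["g1", "g2"]  # all-zero influence, lexicographic
        assert res.final_influence == 0.0

    def test_matches_exhaustive_two_subset_search(self):
        g = generate_graph(GraphSpec(
            num_nodes=8, num_edges=14, random_seed=21,
            color_fractions={"gene": 0.75, "disease": 0.25}))
        diseases = g.nodes_of_color("disease")
        res = query_influencers(g, diseases, k=2, source_color="gene")
        import itertools
        from sipnet.influence import _combine

        def value(pair):
            per = {s: sip_from(g, s) for s in pair}
            return sum(
                _combine((per[s].get(d, 0.0) for s in pair), "noisy_or")
                for d in diseases)
        best = max(value(p) for p in
                   itertools.combinations(g.nodes_of_color("gene"), 2))
        assert res.final_influence == pytest.approx(best)

    def test_reverse_query_swaps_colors(self):
        g = make_graph([("g1", "d1", 0.75), ("g1", "d2", 0.5)],
                       colors={"g1": "gene", "d1": "disease", "d2": "disease"})
        res = query_influencers(g, {"g1"}, k=2, source_color="disease")
        assert sorted(res.seeds) == ["d1", "d2"]


class TestSuiteRelevance:
    def test_direct_edge(self):
        g = make_graph([("g1", "d1", 0.75)],
                       colors={"g1": "gene", "d1": "disease"})
        assert suite_relevance(g, {"g1"}, {"d1"}).relevance == pytest.approx(0.75)

    def test_noisy_or_over_two_genes(self):
        g = make_graph([("g1", "d1", 0.5), ("g2", "d1", 0.5)],
                       colors={"g1": "gene", "g2": "gene", "d1": "disease"})
        rel = suite_relevance(g, {"g1", "g2"}, {"d1"})
        # each gene also reaches d1 through the other (0.25), so the noisy-OR
        # on d1 combines the direct 0.5s: 1 - 0.5*0.5
        assert rel.relevance == pytest.approx(0.75)

    def test_empty_disease_suite_is_zero(self):
        g = make_graph([("g1", "g2", 0.5)])
        assert suite_relevance(g, {"g1"}, set()).relevance == 0.0

    def test_overlapping_suites_rejected(self):
        g = make_graph([("g1", "g2", 0.5)])
        with pytest.raises(ValidationError):
            suite_relevance(g, {"g1"}, {"g1"})


class TestOracles:
    def test_two_node_graph(self):
        g = make_graph([("a", "b", 0.75)])
        assert brute_force_sip(g, "a", "b") == sip(g, "a", "b") == 0.75

    def test_cap_refusal(self):
        g = generate_graph(GraphSpec(num_nodes=12, num_edges=20, random_seed=1))
        with pytest.raises(OracleCapError):
            brute_force_sip(g, *sorted(g.nodes)[:2], cap=10)
        with pytest.raises(OracleCapError):
            brute_force_seeds(g, InfluenceConfig(num_seeds=2), cap=10)

    def test_trace_length_matches_seed_count(self):
        g = generate_graph(GraphSpec(num_nodes=10, num_edges=18, random_seed=4))
        res = select_seeds_greedy(g, InfluenceConfig(num_seeds=4))
        assert len(res.seeds) == len(res.influence_trace) == 4
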