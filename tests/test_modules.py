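"""Module search, modularity, activity scoring, permutation-Gamma null."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from mzactivity.matching import TheoreticalIndex, build_derivative_table
from mzactivity.model_io import to_metabolite_graph
from mzactivity.modules import (
    CandidateModule,
    activity_score,
    agglomerative_split,
    build_null_module_scores,
    default_scorer,
    extract_connecting_subnetworks,
    fit_gamma_mle,
    newman_girvan_modularity,
    prune_protruding_edges,
    score_to_pvalue,
    spectral_split,
)
from mzactivity.modules import _best_bipartition


def _module(nodes, seeds=()):
    return CandidateModule(frozenset(nodes), frozenset(seeds))


class TestConnectingSubnetworks:
    def test_seeds_beyond_reach_yield_nothing(self, two_triangle_graph):
        assert extract_connecting_subnetworks(two_triangle_graph, {"a", "d"}, max_steps=1) == []

    def test_two_step_path_found(self, two_triangle_graph):
        mods = extract_connecting_subnetworks(two_triangle_graph, {"a", "d"}, max_steps=2)
        assert len(mods) == 1
        assert mods[0].nodes == {"a", "c", "d"}
        assert mods[0].seeds == {"a", "d"}

    def test_single_seed_cannot_connect(self, two_triangle_graph):
        assert extract_connecting_subnetworks(two_triangle_graph, {"a"}, max_steps=4) == []

    def test_absent_seeds_silently_dropped(self, two_triangle_graph):
        mods = extract_connecting_subnetworks(two_triangle_graph, {"a", "d", "zz"}, max_steps=2)
        assert len(mods) == 1 and "zz" not in mods[0].nodes

    def test_deeper_search_superset_of_shallow(self, two_triangle_graph):
        shallow = extract_connecting_subnetworks(two_triangle_graph, {"a", "e"}, max_steps=2)
        deep = extract_connecting_subnetworks(two_triangle_graph, {"a", "e"}, max_steps=3)
        got = lambda ms: {m.nodes for m in ms}
        assert got(shallow) <= got(deep)


def _two_cliques(k=4):
    g = nx.disjoint_union(nx.complete_graph(k), nx.complete_graph(k))
    g = nx.relabel_nodes(g, str)
    g.add_edge("0", str(k))
    return g


class TestSpectralSplit:
    def test_clique_is_never_split(self):
        g = nx.relabel_nodes(nx.complete_graph(4), str)
        mod = _module(g.nodes)
        assert spectral_split(mod, g) == [mod]

    def test_bridged_cliques_split_at_the_bridge(self):
        g = _two_cliques(4)
        mod = _module(g.nodes)
        parts = {m.nodes for m in spectral_split(mod, g)}
        assert frozenset(map(str, range(4))) in parts
        assert frozenset(map(str, range(4, 8))) in parts

    def test_tiny_module_unchanged(self):
        g = nx.Graph([("a", "b")])
        mod = _module("ab")
        assert spectral_split(mod, g) == [mod]

    def test_agreement_with_exhaustive_bipartition(self):
        """Best spectral split attains the exhaustive max-modularity value."""
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(4, 11))
            g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(2**31)))
            if not nx.is_connected(g):
                continue
            best = 0.0
            nodes = list(g.nodes)
            for bits in itertools.product([0, 1], repeat=n - 1):
                part = {nodes[0]} | {nodes[i + 1] for i, b in enumerate(bits) if b}
                rest = set(nodes) - part
                if not rest:
                    continue
                best = max(best, nx.community.modularity(g, [part, rest]))
            split = _best_bipartition(g)
            achieved = split[0] if split is not None else 0.0
            assert achieved == pytest.approx(best, abs=1e-9)

    def test_alternative_splitter_also_finds_cliques(self):
        g = _two_cliques(4)
        parts = {m.nodes for m in agglomerative_split(_module(g.nodes), g)}
        assert frozenset(map(str, range(4))) in parts


class TestPruning:
    def test_non_seed_leaf_removed(self):
        g = nx.path_graph(["a", "b", "c"])
        out = prune_protruding_edges(_module("abc", "ab"), {"a", "b"}, g)
        assert out.nodes == {"a", "b"}

    def test_seed_leaves_survive(self):
        g = nx.star_graph(["hub", "a", "b", "c"])
        mod = _module(["hub", "a", "b", "c"], ["a", "b", "c"])
        assert prune_protruding_edges(mod, {"a", "b", "c"}, g).nodes == mod.nodes

    def test_internal_nodes_survive(self):
        g = nx.path_graph(["a", "b", "c", "d"])
        mod = _module("abcd", "ad")
        assert prune_protruding_edges(mod, {"a", "d"}, g).nodes == mod.nodes

    def test_chain_of_leaves_pruned_iteratively(self):
        g = nx.path_graph(["a", "b", "c", "d", "e"])
        out = prune_protruding_edges(_module("abcde", "ab"), {"a", "b"}, g)
        assert out.nodes == {"a", "b"}


class TestModularity:
    def test_triangle_against_whole_network(self, two_triangle_graph):
        q = newman_girvan_modularity(_module("abc", "ab"), two_triangle_graph)
        assert q == pytest.approx(3 / 7 - (7 / 14) ** 2)

    def test_whole_graph_scores_zero(self, two_triangle_graph):
        q = newman_girvan_modularity(_module("abcdef", "ab"), two_triangle_graph)
        assert q == pytest.approx(0.0)

    def test_singleton_penalized_by_degree(self, two_triangle_graph):
        q = newman_girvan_modularity(_module("c"), two_triangle_graph)
        assert q == pytest.approx(-(3 / 14) ** 2)

    def test_empty_network_is_an_error(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        with pytest.raises(ValueError):
            newman_girvan_modularity(_module("ab"), g)

    def test_matches_brute_force_on_random_graphs(self):
        """Q equals a naive double loop over node pairs (adjacency + degrees)."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(3, 13))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            members = [v for v in g.nodes if rng.random() < 0.5] or [0]
            mod = _module(members)
            E = g.number_of_edges()
            e_m = sum(
                1 for u, v in itertools.combinations(members, 2) if g.has_edge(u, v)
            )
            k_sum = sum(sum(1 for w in g.nodes if g.has_edge(v, w)) for v in members)
            expected = e_m / E - (k_sum / (2 * E)) ** 2
            assert newman_girvan_modularity(mod, g) == pytest.approx(expected)


class TestActivityScore:
    def test_declared_example_value(self, two_triangle_graph):
        a = activity_score(_module("abc", "ab"), two_triangle_graph)
        assert a == pytest.approx((2 / 3) * (3 / 7 - 0.25) / np.sqrt(3), abs=1e-5)
        assert a == pytest.approx(0.06873, abs=1e-4)

    def test_strictly_increasing_in_seed_count(self, two_triangle_graph):
        scores = [
            activity_score(_module("abc", seeds), two_triangle_graph)
            for seeds in ("a", "ab", "abc")
        ]
        assert scores[0] < scores[1] < scores[2]

    def test_isomorphism_invariance(self, two_triangle_graph):
        relabel = nx.relabel_nodes(two_triangle_graph, {n: n.upper() for n in two_triangle_graph})
        a1 = activity_score(_module("abc", "ab"), two_triangle_graph)
        a2 = activity_score(_module("ABC", "AB"), relabel)
        assert a1 == pytest.approx(a2)

    def test_seedless_module_rejected(self, two_triangle_graph):
        with pytest.raises(ValueError):
            activity_score(_module("abc"), two_triangle_graph)


class TestGammaNull:
    def test_mle_recovers_generator_parameters(self):
        rng = np.random.default_rng(0)
        draws = stats.gamma.rvs(2.0, scale=3.0, size=10_000, random_state=rng)
        null = fit_gamma_mle(draws)
        assert not null.fallback
        assert 1.9 <= null.shape <= 2.1
        assert 2.85 <= null.scale <= 3.15

    def test_too_few_samples_fall_back(self):
        assert fit_gamma_mle([1.0, 2.0, 1.5, 0.5, 0.9]).fallback

    def test_constant_samples_fall_back(self):
        assert fit_gamma_mle([1.0] * 100).fallback

    def test_non_positive_scores_dropped_and_counted(self):
        rng = np.random.default_rng(1)
        draws = list(stats.gamma.rvs(2.0, scale=1.0, size=100, random_state=rng)) + [-1.0, 0.0]
        null = fit_gamma_mle(draws)
        assert null.n_dropped == 2 and null.n_samples == 100

    def test_all_non_positive_is_fallback_not_crash(self):
        assert fit_gamma_mle([-1.0, -2.0, 0.0]).fallback


class TestScoreToPvalue:
    def test_zero_score_has_unit_pvalue(self):
        null = fit_gamma_mle(stats.gamma.rvs(2.0, scale=1.0, size=1000, random_state=1))
        assert score_to_pvalue(0.0, null) == pytest.approx(1.0)

    def test_monotone_decreasing_in_score(self):
        null = fit_gamma_mle(stats.gamma.rvs(2.0, scale=1.0, size=1000, random_state=1))
        ps = [score_to_pvalue(s, null) for s in np.linspace(0, 30, 50)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))
        assert 0 < ps[-1] < 1 / 1000  # fitted tail extrapolates below 1/n

    def test_fallback_uses_rank_with_add_one(self):
        null = fit_gamma_mle([1.0, 2.0, 3.0])  # below minimum -> fallback
        assert score_to_pvalue(2.5, null) == pytest.approx(2 / 4)
        assert score_to_pvalue(100.0, null) == pytest.approx(1 / 4)


@pytest.fixture(scope="module")
def context(default_fixture):
    model, L_ref, L_sig, _ = default_fixture
    index = TheoreticalIndex(model, build_derivative_table("positive"))
    return to_metabolite_graph(model), index, L_ref, L_sig


class TestNullModuleScores:
    def test_deterministic_under_seed(self, context):
        graph, index, L_ref, L_sig = context
        runs = [
            build_null_module_scores(
                L_ref, 5, len(L_sig), graph=graph, index=index,
                rng=np.random.default_rng(123),
            )
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_zero_permutations_rejected(self, context):
        graph, index, L_ref, L_sig = context
        with pytest.raises(ValueError):
            build_null_module_scores(L_ref, 0, 5, graph=graph, index=index)

    def test_oversized_draw_rejected(self, context):
        graph, index, L_ref, _ = context
        with pytest.raises(ValueError):
            build_null_module_scores(L_ref, 1, len(L_ref) + 1, graph=graph, index=index)
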