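"""Sharing rules, bipartite assembly, the compact weighted network,
thresholding and topology statistics."""

import math

import networkx as nx
import numpy as np
import pytest

from ddsn.corpus import Disease, PhenotypicSeries, build_corpus
from ddsn.errors import ComputationError
from ddsn.network import (
    SharedPhenotype,
    apply_threshold,
    build_bipartite,
    degree_stats,
    derive_network,
    giant_component,
    shared_dp_stats,
    shared_phenotypes_pair,
    threshold_sweep,
)
from ddsn.ontology import ICTable, compute_ic

from ._oracles import (
    corpus_from,
    dag_from_parents,
    naive_network,
    naive_shared,
    random_annotations,
    random_parents,
)

LOG32 = math.log(3 / 2) / math.log(3)


@pytest.fixture(scope="module")
def fig1_net(fig1):
    diseases = {d: Disease(id=d) for d in fig1["annotations"]}
    corpus = build_corpus(diseases, fig1["series"], fig1["annotations"], fig1["ic"])
    tuples, bipartite, fractions = build_bipartite(corpus, fig1["dag"])
    net = derive_network(tuples, fig1["ic"])
    return {
        "corpus": corpus,
        "tuples": tuples,
        "bipartite": bipartite,
        "fractions": fractions,
        "net": net,
    }


class TestSharingRules:
    def test_worked_example_pairs(self, fig1):
        dag, ann = fig1["dag"], fig1["annotations"]
        assert shared_phenotypes_pair(dag, ann["A"], ann["B"]) == {"1": 1}
        assert shared_phenotypes_pair(dag, ann["A"], ann["C"]) == {"4": 2}
        # distant common ancestors (here the root) never create a share
        assert shared_phenotypes_pair(dag, ann["B"], ann["C"]) == {}

    def test_parent_child_rule(self, fig1):
        dag = fig1["dag"]
        assert shared_phenotypes_pair(dag, {"4"}, {"2"}) == {"4": 3}
        assert shared_phenotypes_pair(dag, {"2"}, {"4"}) == {"4": 3}

    def test_lowest_rule_wins_on_multiple_routes(self, fig1):
        dag = fig1["dag"]
        # 4 is shared identically (rule 1) and as parent of 2 (rule 3)
        assert shared_phenotypes_pair(dag, {"4", "2"}, {"4"}) == {"4": 1}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_rules(self, seed):
        rng = np.random.default_rng(400 + seed)
        parents = random_parents(rng, 30)
        dag = dag_from_parents(parents)
        a = set(np.random.default_rng(seed).choice(sorted(parents), 4))
        b = set(np.random.default_rng(seed + 1).choice(sorted(parents), 4))
        assert shared_phenotypes_pair(dag, a, b) == naive_shared(parents, a, b)


class TestBipartite:
    def test_worked_example_graph(self, fig1_net):
        bip = fig1_net["bipartite"]
        assert set(bip.nodes) == {"A", "B", "C", "1", "4"}
        assert set(map(frozenset, bip.edges)) == {
            frozenset({"A", "1"}),
            frozenset({"B", "1"}),
            frozenset({"A", "4"}),
            frozenset({"C", "4"}),
        }
        assert bip.degree("A") == 2 and bip.degree("B") == 1 and bip.degree("C") == 1

    def test_worked_example_tuples(self, fig1_net):
        assert fig1_net["tuples"] == [
            SharedPhenotype("A", "PS1", "1", "1", 1, "B", "PS1", "1"),
            SharedPhenotype("A", "PS1", "2", "4", 2, "C", "PS2", "3"),
        ]

    def test_single_disease_corpus(self, fig1):
        annotations = {"A": {"1"}, "Zz": {"3"}}
        diseases = {d: Disease(id=d) for d in annotations}
        series = {"P": PhenotypicSeries(id="P", members={"A"})}
        ic = compute_ic(fig1["dag"], annotations)
        corpus = build_corpus(diseases, series, annotations, ic)
        tuples, bip, _ = build_bipartite(corpus, fig1["dag"])
        assert tuples == [] and bip.number_of_nodes() == 0


class TestDeriveNetwork:
    def test_worked_example_edges(self, fig1_net):
        net = fig1_net["net"]
        edges = {
            tuple(sorted((u, v))): (d["w"], d["n_shared"])
            for u, v, d in net.edges(data=True)
        }
        assert set(edges) == {("A", "B"), ("A", "C")}
        assert edges[("A", "B")][0] == pytest.approx(LOG32, abs=1e-12)
        assert edges[("A", "C")][0] == pytest.approx(LOG32, abs=1e-12)
        assert edges[("A", "B")][1] == 1

    def test_weight_is_mean_of_distinct_terms(self):
        tuples = [
            SharedPhenotype("X", "P", "a", "s1", 1, "Y", "P", "a"),
            SharedPhenotype("X", "P", "b", "s2", 2, "Y", "P", "c"),
            SharedPhenotype("X", "P", "d", "s2", 2, "Y", "P", "e"),  # dup term
        ]
        ic = ICTable(ic={"s1": 1.0, "s2": 0.5}, n_diseases=4)
        net = derive_network(tuples, ic)
        data = net.get_edge_data("X", "Y")
        assert data["n_shared"] == 2
        assert data["w"] == pytest.approx(0.75)

    def test_missing_ic_raises(self):
        tuples = [SharedPhenotype("X", "P", "a", "s1", 1, "Y", "P", "a")]
        with pytest.raises(ComputationError):
            derive_network(tuples, ICTable(ic={}, n_diseases=2))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_evaluator(self, seed):
        rng = np.random.default_rng(500 + seed)
        parents = random_parents(rng, 25)
        dag = dag_from_parents(parents)
        annotations = random_annotations(rng, parents, 12, max_terms=4)
        ic = compute_ic(dag, annotations)
        corpus = corpus_from(dag, annotations, ic)
        tuples, _, _ = build_bipartite(corpus, dag)
        net = derive_network(tuples, ic)
        expected = naive_network(parents, ic.ic, annotations)
        got = {
            tuple(sorted((u, v))): (d["n_shared"], d["w"], d["shared_terms"])
            for u, v, d in net.edges(data=True)
        }
        assert set(got) == set(expected)
        for pair, (n, w, terms) in expected.items():
            assert got[pair][0] == n
            assert got[pair][1] == pytest.approx(w, abs=1e-12)
            assert got[pair][2] == terms

    def test_identical_same_ps_annotations_always_linked(self, fig1):
        # rule 1 guarantees an edge for same-series identical annotation sets
        annotations = {"X": {"2", "3"}, "Y": {"2", "3"}}
        diseases = {d: Disease(id=d) for d in annotations}
        series = {"P": PhenotypicSeries(id="P", members={"X", "Y"})}
        ic = compute_ic(fig1["dag"], annotations)
        corpus = build_corpus(diseases, series, annotations, ic)
        tuples, _, _ = build_bipartite(corpus, fig1["dag"])
        net = derive_network(tuples, ic)
        assert net.has_edge("X", "Y")


class TestSharedDPStats:
    def test_worked_example_strata(self, fig1_net):
        stats = shared_dp_stats(
            fig1_net["net"], fig1_net["corpus"].disease_ps()
        )
        assert stats.loc["same_ps", "n_pairs"] == 1
        assert stats.loc["diff_ps", "n_pairs"] == 1
        assert stats.loc["all", "n_pairs"] == 2
        assert stats.loc["same_ps", "ic_mean"] == pytest.approx(LOG32, abs=1e-9)
        assert stats.loc["same_ps", "n_shared_mean"] == 1.0

    def test_empty_stratum_row_emitted(self, fig1_net):
        everyone_same = {d: {"P"} for d in fig1_net["net"].nodes}
        stats = shared_dp_stats(fig1_net["net"], everyone_same)
        assert stats.loc["diff_ps", "n_pairs"] == 0
        assert math.isnan(stats.loc["diff_ps", "ic_mean"])


class TestThreshold:
    def test_zero_threshold_is_identity(self, fig1_net):
        sub, report = apply_threshold(fig1_net["net"], 0.0)
        assert report["edge_fraction"] == 1.0 and report["node_fraction"] == 1.0
        assert sub.number_of_edges() == fig1_net["net"].number_of_edges()

    def test_high_threshold_empties_worked_example(self, fig1_net):
        sub, report = apply_threshold(fig1_net["net"], 0.5)
        assert sub.number_of_edges() == 0 and sub.number_of_nodes() == 0

    def test_strictness_at_the_boundary(self, fig1_net):
        # comparison is strictly greater-than, so w_star == w removes the edge
        sub, _ = apply_threshold(fig1_net["net"], LOG32)
        assert sub.number_of_edges() == 0

    def test_sweep_monotone(self, fig1_net):
        sweep = threshold_sweep(fig1_net["net"], [0.0, 0.2, 0.4, 0.6, 0.8])
        assert (sweep["edge_fraction"].diff().dropna() <= 0).all()
        assert (sweep["node_fraction"].diff().dropna() <= 0).all()


class TestDegreeAndComponents:
    def test_worked_example_degree_means(self, fig1_net):
        stats = degree_stats(fig1_net["bipartite"])
        assert stats["disease"]["degree_mean"] == pytest.approx(4 / 3)
        assert stats["phenotype"]["degree_mean"] == pytest.approx(2.0)

    def test_star_hub(self):
        g = nx.star_graph(5)  # node 0 with 5 leaves
        stats = degree_stats(g)
        assert stats["all"]["hubs"][0] == (0, 5)

    def test_degrees_match_adjacency_row_sums(self):
        g = nx.gnp_random_graph(15, 0.3, seed=4)
        stats = degree_stats(g)
        adj = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
        assert stats["all"]["degree_mean"] == pytest.approx(adj.sum(axis=1).mean())

    def test_giant_component_worked_example(self, fig1_net):
        report = giant_component(fig1_net["net"])
        assert report["n_components"] == 1
        assert report["giant_nodes"] == 3 and report["giant_edges"] == 2

    def test_two_planted_clusters_stay_separate(self, fig1):
        # annotations under disjoint branches that share no direct parent
        annotations = {"P": {"1"}, "Q": {"1"}, "R": {"2"}, "S": {"2"}}
        diseases = {d: Disease(id=d) for d in annotations}
        series = {
            "S1": PhenotypicSeries(id="S1", members={"P", "Q"}),
            "S2": PhenotypicSeries(id="S2", members={"R", "S"}),
        }
        ic = compute_ic(fig1["dag"], annotations)
        corpus = build_corpus(diseases, series, annotations, ic)
        tuples, _, _ = build_bipartite(corpus, fig1["dag"])
        net = derive_network(tuples, ic)
        report = giant_component(net)
        assert report["n_components"] == 2

    def test_edgeless_network_components(self):
        g = nx.empty_graph(4)
        report = giant_component(g)
        assert report["sizes"] == [1, 1, 1, 1]
        assert report["giant_nodes"] == 1 and report["giant_edges"] == 0
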