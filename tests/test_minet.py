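"""Mutual information, G-test significance, network inference and MCODE."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dnmeta import (
    MIEdge,
    SimulationConfig,
    UsageError,
    combat_adjust,
    generate_multiset,
    hub_ranking,
    infer_network,
    mcode_cluster,
    merge_common_genes,
    mi_pvalue,
    mi_pvalue_permutation,
    mutual_information,
    williams_q,
)


class TestMutualInformation:
    def test_perfect_dependence_reaches_log2_bins(self, rng):
        x = rng.permutation(np.arange(60, dtype=float))
        for b in (2, 3, 5):
            assert mutual_information(x, x, b) == pytest.approx(np.log2(b))

    def test_constant_vector_gives_zero_with_warning(self):
        x = np.arange(30, dtype=float)
        with pytest.warns(UserWarning):
            assert mutual_information(x, np.ones(30), 3) == 0.0

    def test_hand_computed_two_by_two_table(self):
        # joint counts [[20,5],[5,20]] over n=50, B=2
        x = np.concatenate([np.zeros(25), np.ones(25)])
        y = np.concatenate([np.zeros(20), np.ones(5), np.zeros(5), np.ones(20)])
        # add tiny increasing jitter to make values distinct but keep bins
        x = x + np.linspace(0, 0.4, 50)
        y = y + np.linspace(0, 0.4, 50)
        mi = mutual_information(x, y, 2)
        expected = sum(
            c / 50 * np.log2((c / 50) / 0.25)
            for c in (20, 5, 5, 20)
        )
        assert mi == pytest.approx(expected, abs=1e-12)
        assert mi == pytest.approx(0.2781, abs=5e-4)

    def test_symmetry_and_upper_bound(self, rng):
        for _ in range(10):
            x = rng.normal(size=40)
            y = 0.5 * x + rng.normal(size=40)
            b = 3
            assert mutual_information(x, y, b) == mutual_information(y, x, b)
            assert 0 <= mutual_information(x, y, b) <= np.log2(b) + 1e-12

    def test_unequal_lengths_rejected(self):
        with pytest.raises(UsageError):
            mutual_information(np.arange(10.0), np.arange(9.0), 2)


class TestMiPvalue:
    def test_zero_mi_gives_p_one(self):
        edge = MIEdge("a", "b", 0.0, 50, 2)
        assert mi_pvalue(edge) == 1.0

    def test_hand_example_g_statistic_and_chi2_tail(self):
        edge = MIEdge("a", "b", 0.27807190511263773, 50, 2)
        assert edge.g_statistic == pytest.approx(19.277, abs=5e-3)
        assert edge.df == 1
        # plain chi-square tail of G at 1 df
        assert mi_pvalue(edge, williams=False) == pytest.approx(
            stats.chi2.sf(19.277, 1), rel=5e-3)
        assert mi_pvalue(edge, williams=False) == pytest.approx(1.1e-5, abs=3e-6)
        # the small-sample corrected default is close but less extreme
        assert mi_pvalue(edge) > mi_pvalue(edge, williams=False)

    def test_analytic_p_tracks_permutation_p(self, rng):
        """Analytic null agrees with the permutation null.

        The G statistic is discrete at n=60, so the continuous chi-square
        tail can differ from the exact conditional (permutation) p by a few
        percent in the body of the distribution; the check allows for that
        discreteness on top of the permutation sampling band, and separately
        requires the two nulls to reject at the same rate at alpha = 0.1.
        """
        n, b, e = 60, 3, 1000
        inside = 0
        n_pairs = 100
        analytic_p, perm_p = [], []
        for i in range(n_pairs):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            mi = mutual_information(x, y, b)
            analytic = mi_pvalue(MIEdge("a", "b", mi, n, b))
            perm = mi_pvalue_permutation(x, y, b, n_permutations=e,
                                         seed=int(rng.integers(2**31)))
            analytic_p.append(analytic)
            perm_p.append(perm)
            band = 1.96 * np.sqrt(analytic * (1 - analytic) / e) + 1.5 / e
            if abs(analytic - perm) <= band + 0.04:
                inside += 1
        assert inside / n_pairs >= 0.95
        a_rate = np.mean(np.asarray(analytic_p) < 0.1)
        p_rate = np.mean(np.asarray(perm_p) < 0.1)
        assert abs(a_rate - p_rate) <= 0.05


class TestInferNetwork:
    def test_independent_genes_give_no_edges(self, rng):
        zero_edge_seeds = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            m = pd.DataFrame(r.normal(size=(50, 40)),
                             index=[f"g{i}" for i in range(50)])
            net = infer_network(m, p_threshold=1e-7)
            if net.graph.number_of_edges() == 0:
                zero_edge_seeds += 1
        assert zero_edge_seeds >= 19

    def test_perfectly_dependent_pair_is_single_edge(self, rng):
        x = rng.normal(size=60)
        m = pd.DataFrame([x, 2 * x + 1], index=["a", "b"])
        net = infer_network(m, bins=3)
        assert net.graph.number_of_edges() == 1
        assert set(net.edges[["gene_a", "gene_b"]].iloc[0]) == {"a", "b"}

    def test_bins_reduced_for_small_cohorts(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 10)))
        with pytest.warns(UserWarning, match="reducing bins"):
            net = infer_network(m, bins=5)
        assert net.bins == 3

    def test_planted_module_recovered_at_study_scale(self):
        """Module detection measured on the merged + batch-adjusted bundle."""
        cfg = SimulationConfig(seed=3, n_outlier_arrays=0, n_duplicate_pairs=0)
        datasets, truth = generate_multiset(cfg)
        voting = [d for d in datasets if d.tissue != "cortex"]
        adjusted, _ = combat_adjust(merge_common_genes(voting))
        module = sorted(truth.module_genes)
        background = [g for g in adjusted.genes
                      if g not in truth.module_genes
                      and g not in truth.all_de_genes()][:80]
        net = infer_network(adjusted.expr.loc[module + background])
        mod = set(module)
        within = sum(r.gene_a in mod and r.gene_b in mod
                     for r in net.edges.itertuples())
        background_edges = len(net.edges) - within
        n_mod_pairs = len(module) * (len(module) - 1) / 2
        n_all = len(module + background)
        n_bg_pairs = n_all * (n_all - 1) / 2 - n_mod_pairs
        assert within / n_mod_pairs >= 0.8
        assert background_edges / n_bg_pairs <= 0.01
        # planted module returned as the top-scoring dense complex
        top = mcode_cluster(net)[0]
        assert len(set(top.members) & mod) / len(top.members) >= 0.9


def clique_with_pendant_path():
    g = nx.Graph()
    clique = ["c1", "c2", "c3", "c4", "c5"]
    for i, a in enumerate(clique):
        for b in clique[i + 1:]:
            g.add_edge(a, b)
    g.add_edges_from([("c1", "p1"), ("p1", "p2"), ("p2", "p3")])
    return g, clique


class TestMcode:
    def test_five_clique_with_pendant_path(self):
        g, clique = clique_with_pendant_path()
        complexes = mcode_cluster(g)
        top = complexes[0]
        assert top.members == sorted(clique)
        assert top.score == pytest.approx(5.0)
        assert top.density == pytest.approx(1.0)

    def test_edgeless_graph_no_complexes(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        assert mcode_cluster(g) == []

    def test_disjoint_cliques_ranked_by_score(self):
        g = nx.Graph()
        six = [f"a{i}" for i in range(6)]
        four = [f"b{i}" for i in range(4)]
        for grp in (six, four):
            for i, u in enumerate(grp):
                for v in grp[i + 1:]:
                    g.add_edge(u, v)
        complexes = mcode_cluster(g)
        assert len(complexes) == 2
        assert complexes[0].members == six
        assert complexes[0].score == pytest.approx(6.0)
        assert complexes[1].members == four
        assert complexes[1].score == pytest.approx(4.0)

    def test_complexes_are_disjoint_and_connected(self, rng):
        g = nx.gnp_random_graph(40, 0.15, seed=5)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        complexes = mcode_cluster(g)
        seen = set()
        for c in complexes:
            assert not (set(c.members) & seen)
            seen |= set(c.members)
            assert nx.is_connected(g.subgraph(c.members))

    def test_complex_density_at_least_network_density(self):
        cfg = SimulationConfig(seed=12, n_outlier_arrays=0,
                               n_duplicate_pairs=0, n_genes=400,
                               n_de_genes_per_compartment=50)
        datasets, truth = generate_multiset(cfg)
        voting = [d for d in datasets if d.tissue != "cortex"]
        adjusted, _ = combat_adjust(merge_common_genes(voting))
        genes = sorted(truth.module_genes) + [
            g for g in adjusted.genes if g not in truth.module_genes][:60]
        net = infer_network(adjusted.expr.loc[genes])
        full_density = nx.density(net.graph)
        for c in mcode_cluster(net):
            assert c.density >= full_density - 1e-12


class TestHubs:
    def test_star_center_ranked_first(self):
        g = nx.star_graph(10)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        hubs = hub_ranking(g)
        assert hubs.index[0] == "n0"
        assert hubs.iloc[0] == 10

    def test_ring_ties_broken_lexicographically(self):
        g = nx.cycle_graph(5)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        hubs = hub_ranking(g)
        assert list(hubs.index) == sorted(hubs.index)
        assert (hubs == 2).all()

    def test_high_loading_module_gene_is_top_hub(self, rng):
        n = 80
        f = rng.normal(size=n)
        loadings = np.linspace(0.5, 1.0, 15)
        x = np.vstack(
            [lam * f + rng.normal(0, 0.4, n) for lam in loadings]
            + [rng.normal(size=n) for _ in range(30)]
        )
        names = [f"m{i:02d}" for i in range(15)] + [f"b{i:02d}" for i in range(30)]
        net = infer_network(pd.DataFrame(x, index=names))
        hubs = hub_ranking(net, top_n=5)
        top3_loading = {"m12", "m13", "m14"}
        assert top3_loading & set(hubs.index)

    def test_empty_network_rejected(self):
        with pytest.raises(UsageError):
            hub_ranking(nx.Graph())
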