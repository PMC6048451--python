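import itertools

import networkx as nx
import numpy as np
import pytest

from rewirekit import datagen
from rewirekit.exprio import ExpressionMatrix
from rewirekit.matequiv import CorrMatrix
from rewirekit.netarch import (
    CentralityRecord,
    GeneNetwork,
    build_network,
    centralities,
    centrality_correlation,
    consensus_hub,
    count_known_edges,
    count_significant_pairs,
    differential_correlation,
    strong_edges,
    tail_quantile,
)


def _star_network(n_leaves=3, weight=1.0):
    G = nx.Graph()
    G.add_node("hub")
    for i in range(n_leaves):
        G.add_edge("hub", f"leaf{i}", weight=weight, r=np.sqrt(weight),
                   p=0.01, distance=1.0 / weight)
    corr = CorrMatrix(["hub"] + [f"leaf{i}" for i in range(n_leaves)],
                      np.eye(n_leaves + 1), 10)
    return GeneNetwork(graph=G, alpha=0.05, corr=corr)


class TestBuildNetwork:
    def test_edge_rule(self, rewired_cohort):
        matrix, labels = rewired_cohort
        sub = matrix.select_samples(labels == 0)
        net = build_network(sub, alpha=0.05)
        for u, v, d in net.graph.edges(data=True):
            assert d["p"] <= 0.05
            assert d["weight"] == pytest.approx(d["r"] ** 2)
            assert 0 < d["weight"] <= 1

    def test_isolated_nodes_kept(self, rng):
        values = rng.normal(size=(5, 30))
        m = ExpressionMatrix([f"g{i}" for i in range(5)],
                             [f"s{j}" for j in range(30)], values)
        net = build_network(m, alpha=1e-9)
        assert set(net.nodes) == set(m.gene_ids)

    def test_three_samples_rejected(self, rng):
        m = ExpressionMatrix(["a", "b"], ["s1", "s2", "s3"], rng.normal(size=(2, 3)))
        with pytest.raises(ValueError, match="4 samples"):
            build_network(m)

    def test_edge_set_shrinks_with_alpha(self, rewired_cohort):
        matrix, labels = rewired_cohort
        sub = matrix.select_samples(labels == 0)
        counts = [build_network(sub, alpha=a).n_edges for a in (0.2, 0.05, 0.001)]
        assert counts[0] >= counts[1] >= counts[2]


class TestCentralities:
    def test_star_degree_betweenness(self):
        # K_{1,3} exhaustive path oracle: 3 leaf pairs all route via hub
        recs = {r.gene: r for r in centralities(_star_network())}
        assert recs["hub"].degree == pytest.approx(3.0)
        assert recs["hub"].betweenness == pytest.approx(3.0)
        for i in range(3):
            assert recs[f"leaf{i}"].degree == pytest.approx(1.0)
            assert recs[f"leaf{i}"].betweenness == 0.0

    def test_star_eigenvector_closed_form(self):
        recs = {r.gene: r for r in centralities(_star_network())}
        assert recs["hub"].eigenvector == pytest.approx(1.0)
        for i in range(3):
            assert recs[f"leaf{i}"].eigenvector == pytest.approx(1 / np.sqrt(3))

    def test_closeness_wasserman_faust(self):
        recs = {r.gene: r for r in centralities(_star_network())}
        # hub: distances (1,1,1) -> (4-1)^2/((4-1)*3)... reachable=4
        assert recs["hub"].closeness == pytest.approx(1.0)
        # leaf: distances (1,2,2) -> (3)^2/(3*5)
        assert recs["leaf0"].closeness == pytest.approx(9.0 / 15.0)

    def test_degree_equals_weight_row_sums(self, rewired_cohort):
        matrix, labels = rewired_cohort
        net = build_network(matrix.select_samples(labels == 0))
        W = nx.to_numpy_array(net.graph, nodelist=net.nodes, weight="weight")
        recs = {r.gene: r for r in centralities(net)}
        for i, g in enumerate(net.nodes):
            assert recs[g].degree == pytest.approx(W[i].sum(), abs=1e-12)

    def test_relabeling_invariance(self):
        net = _star_network()
        base = sorted(
            (r.degree, r.closeness, r.betweenness, r.eigenvector)
            for r in centralities(net)
        )
        relabeled = nx.relabel_nodes(net.graph, {n: f"x_{n}" for n in net.graph})
        net2 = GeneNetwork(graph=relabeled, alpha=0.05, corr=net.corr)
        other = sorted(
            (r.degree, r.closeness, r.betweenness, r.eigenvector)
            for r in centralities(net2)
        )
        assert base == pytest.approx(other)

    def test_empty_network_warns_zeroes(self):
        G = nx.Graph()
        G.add_nodes_from(["a", "b"])
        net = GeneNetwork(graph=G, alpha=0.05,
                          corr=CorrMatrix(["a", "b"], np.eye(2), 10))
        with pytest.warns(UserWarning, match="no edges"):
            recs = centralities(net)
        assert all(r.degree == r.betweenness == r.eigenvector == 0 for r in recs)

    def test_betweenness_matches_exhaustive_enumeration(self, rng):
        # brute-force Brandes oracle on a random weighted 6-node graph
        nodes = list("abcdef")
        G = nx.Graph()
        G.add_nodes_from(nodes)
        for u, v in itertools.combinations(nodes, 2):
            if rng.uniform() < 0.6:
                w = rng.uniform(0.2, 1.0)
                G.add_edge(u, v, weight=w, distance=1.0 / w)
        net = GeneNetwork(graph=G, alpha=0.05,
                          corr=CorrMatrix(nodes, np.eye(6), 10))

        def brute_betweenness():
            score = {v: 0.0 for v in nodes}
            for s, t in itertools.combinations(nodes, 2):
                paths = []
                for k in range(len(nodes)):
                    for middle in itertools.permutations(
                        [x for x in nodes if x not in (s, t)], k
                    ):
                        path = (s, *middle, t)
                        if all(G.has_edge(a, b) for a, b in zip(path, path[1:])):
                            length = sum(
                                G[a][b]["distance"] for a, b in zip(path, path[1:])
                            )
                            paths.append((length, path))
                if not paths:
                    continue
                best = min(length for length, _ in paths)
                shortest = [p for length, p in paths if length < best + 1e-12]
                for _, *middle, _ in shortest:
                    for v in middle:
                        score[v] += 1.0 / len(shortest)
            return score

        expected = brute_betweenness()
        got = {r.gene: r.betweenness for r in centralities(net)}
        for v in nodes:
            assert got[v] == pytest.approx(expected[v], abs=1e-9)


class TestConsensusHub:
    def _records(self, rows):
        return [CentralityRecord(g, *vals) for g, vals in rows.items()]

    def test_unanimous(self):
        recs = self._records({"A": (3, 3, 3, 1.0), "B": (1, 1, 1, 0.5)})
        consensus, per_metric = consensus_hub(recs)
        assert consensus == ["A"]
        assert all(v == ["A"] for v in per_metric.values())

    def test_mode_2_1_1(self):
        recs = self._records({
            "A": (5, 0.1, 0.0, 1.0),   # top degree + top eigenvector
            "B": (1, 0.9, 0.0, 0.2),   # top closeness
            "C": (1, 0.1, 7.0, 0.2),   # top betweenness
        })
        consensus, _ = consensus_hub(recs)
        assert consensus == ["A"]

    def test_tie_reports_both(self):
        recs = self._records({
            "A": (5, 0.9, 0.0, 0.1),   # degree + closeness
            "B": (1, 0.1, 7.0, 1.0),   # betweenness + eigenvector
        })
        consensus, _ = consensus_hub(recs)
        assert consensus == ["A", "B"]


class TestCentralityCorrelation:
    def _random_records(self, rng, genes):
        return [
            CentralityRecord(g, rng.uniform(), rng.uniform(), rng.uniform(), rng.uniform())
            for g in genes
        ]

    def test_self_correlation_one(self, rng):
        recs = self._random_records(rng, [f"g{i}" for i in range(10)])
        out = centrality_correlation(recs, recs)
        for metric in ("degree", "closeness", "betweenness", "eigenvector", "average"):
            assert out[metric] == pytest.approx(1.0)

    def test_independent_near_zero(self, rng):
        genes = [f"g{i}" for i in range(1000)]
        a = self._random_records(rng, genes)
        b = self._random_records(rng, genes)
        out = centrality_correlation(a, b)
        assert abs(out["average"]) < 0.1

    def test_constant_metric_excluded_with_warning(self, rng):
        genes = [f"g{i}" for i in range(10)]
        a = self._random_records(rng, genes)
        b = [CentralityRecord(g, 1.0, rng.uniform(), rng.uniform(), rng.uniform())
             for g in genes]
        with pytest.warns(UserWarning, match="constant"):
            out = centrality_correlation(a, b)
        assert np.isnan(out["degree"])
        assert np.isfinite(out["average"])

    def test_too_few_shared(self, rng):
        a = self._random_records(rng, ["x", "y"])
        with pytest.raises(ValueError, match="shared"):
            centrality_correlation(a, a)


class TestCountSignificantPairs:
    def test_identical_groups(self, rewired_cohort):
        matrix, labels = rewired_cohort
        sub = matrix.select_samples(labels == 0)
        out = count_significant_pairs(sub, sub)
        assert out["count_shared"] == out["count_a"] == out["count_b"]

    def test_bonferroni_calibration(self):
        # independent noise: expected significant count ~ alpha in total
        total = 0
        for rep in range(20):
            spec = datagen.RewiringSpec(
                n_genes=50, group_sizes=[100, 100],
                corr_matrices=[np.eye(50), np.eye(50)], seed=500 + rep,
            )
            m, labels = datagen.generate_rewired_cohort(spec)
            out = count_significant_pairs(
                m.select_samples(labels == 0), m.select_samples(labels == 1)
            )
            total += out["count_a"] + out["count_b"]
        assert total <= 3

    def test_planted_block_power(self):
        spec = datagen.RewiringSpec(
            n_genes=10, group_sizes=[200, 200],
            corr_matrices=[datagen.block_corr(10, slice(0, 10), 0.9), np.eye(10)],
            seed=9,
        )
        m, labels = datagen.generate_rewired_cohort(spec)
        out = count_significant_pairs(
            m.select_samples(labels == 0), m.select_samples(labels == 1)
        )
        assert out["count_a"] == 45
        assert out["count_b"] <= 2

    def test_mismatched_universe(self, rng):
        a = ExpressionMatrix(["x", "y"], ["s1", "s2", "s3", "s4"], rng.normal(size=(2, 4)))
        b = ExpressionMatrix(["x", "z"], ["s1", "s2", "s3", "s4"], rng.normal(size=(2, 4)))
        with pytest.raises(ValueError, match="universe"):
            count_significant_pairs(a, b)


class TestDifferentialCorrelation:
    def _cm(self, r, n):
        M = np.array([[1.0, r], [r, 1.0]])
        return CorrMatrix(["a", "b"], M, n)

    def test_equal_correlations(self):
        rows = differential_correlation(self._cm(0.5, 103), self._cm(0.5, 103))
        assert rows[0]["z"] == 0.0
        assert rows[0]["p"] == pytest.approx(1.0)

    def test_hand_computed_z(self):
        rows = differential_correlation(self._cm(0.5, 103), self._cm(0.0, 103))
        assert rows[0]["z"] == pytest.approx(np.arctanh(0.5) / np.sqrt(0.02), rel=1e-12)
        assert rows[0]["z"] == pytest.approx(3.884, abs=2e-3)

    def test_null_z_standard_normal(self, rng):
        from scipy.stats import kstest

        n = 150
        zs = []
        while len(zs) < 1000:
            x = rng.standard_normal((2, n))
            y = rng.standard_normal((2, n))
            r1 = np.corrcoef(x)[0, 1]
            r2 = np.corrcoef(y)[0, 1]
            zs.append((np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(2.0 / (n - 3)))
        assert kstest(zs, "norm").pvalue > 0.01

    def test_perfect_corr_named(self):
        M = np.array([[1.0, 1.0], [1.0, 1.0]])
        bad = CorrMatrix(["a", "b"], M, 10)
        with pytest.raises(ValueError, match=r"\(a, b\)"):
            differential_correlation(bad, self._cm(0.0, 10))


class TestStrongEdges:
    def test_strict_threshold(self):
        M = np.array([
            [1.0, 0.70, 0.71],
            [0.70, 1.0, -0.8],
            [0.71, -0.8, 1.0],
        ])
        R = CorrMatrix(["a", "b", "c"], M, 20)
        pairs = strong_edges(R, threshold=0.7)
        got = {(p[0], p[1]) for p in pairs}
        assert got == {("a", "c"), ("b", "c")}  # 0.70 exactly excluded

    def test_quantile_constant(self):
        assert tail_quantile(np.full(10, 0.3)) == pytest.approx(0.3)

    def test_quantile_hand_computed(self):
        values = np.arange(0.01, 1.005, 0.01)
        assert tail_quantile(values, 0.95) == pytest.approx(0.9505)


class TestCountKnownEdges:
    def test_empty_table(self):
        assert count_known_edges([("A", "B", 0.9)], []) == (0, 1)

    def test_full_table(self):
        pairs = [("A", "B", 0.9), ("C", "D", -0.8)]
        table = [("A", "B"), ("C", "D")]
        assert count_known_edges(pairs, table) == (2, 2)

    def test_order_insensitive(self):
        assert count_known_edges([("A", "B"), ("C", "D")], [("B", "A")]) == (1, 2)
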