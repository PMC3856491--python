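import math

import numpy as np
import pandas as pd
import pytest

from gepess import features as ft
from gepess.io import InteractionNetwork

import oracles
from conftest import k3, k4, path3, random_network, star3


class TestCentralityExamples:
    def test_degree(self):
        assert ft.degree_centrality(k3()) == {"A": 2, "B": 2, "C": 2}
        assert ft.degree_centrality(path3()) == {"A": 1, "B": 2, "C": 1}

    def test_betweenness(self):
        assert all(v == 0 for v in ft.betweenness_centrality(k3()).values())
        assert ft.betweenness_centrality(path3())["B"] == pytest.approx(1.0)
        assert ft.betweenness_centrality(star3())["S"] == pytest.approx(3.0)

    def test_closeness(self):
        assert all(v == pytest.approx(1.0) for v in ft.closeness_centrality(k3()).values())
        cc = ft.closeness_centrality(path3())
        assert cc["B"] == pytest.approx(1.0)
        assert cc["A"] == pytest.approx(2 / 3)
        iso = InteractionNetwork.from_edges([("A", "B")], nodes=["Z"])
        assert ft.closeness_centrality(iso)["Z"] == 0.0

    def test_subgraph(self):
        iso = InteractionNetwork.from_edges([], nodes=["Z"])
        assert ft.subgraph_centrality(iso)["Z"] == pytest.approx(1.0)
        edge = InteractionNetwork.from_edges([("A", "B")])
        assert ft.subgraph_centrality(edge)["A"] == pytest.approx(math.cosh(1.0), abs=1e-8)
        expected = (math.e ** 2 + 2 / math.e) / 3  # eigenvalues {2, -1, -1}
        assert ft.subgraph_centrality(k3())["A"] == pytest.approx(expected, abs=1e-8)

    def test_eigenvector(self):
        ec = ft.eigenvector_centrality(k3())
        assert all(v == pytest.approx(1 / math.sqrt(3)) for v in ec.values())
        ec = ft.eigenvector_centrality(star3())
        assert ec["S"] == pytest.approx(1 / math.sqrt(2), abs=1e-8)
        assert ec["L1"] == pytest.approx(1 / math.sqrt(6), abs=1e-8)
        # nodes outside the largest component score 0
        net = InteractionNetwork.from_edges([("A", "B"), ("B", "C"), ("X", "Y")])
        assert ft.eigenvector_centrality(net)["X"] == 0.0
        with pytest.raises(ValueError):
            ft.eigenvector_centrality(InteractionNetwork())

    def test_information(self):
        ic = ft.information_centrality(k3())
        assert len(set(round(v, 12) for v in ic.values())) == 1  # vertex-transitive
        icp = ft.information_centrality(path3())
        assert icp["B"] > icp["A"]
        ics = ft.information_centrality(star3())
        assert ics["S"] > max(ics[f"L{i}"] for i in (1, 2, 3))
        iso = InteractionNetwork.from_edges([("A", "B")], nodes=["Z"])
        assert ft.information_centrality(iso)["Z"] == 0.0

    def test_nc(self):
        assert all(v == pytest.approx(2.0) for v in ft.nc_centrality(k3()).values())
        assert ft.nc_centrality(star3())["S"] == 0.0
        assert all(v == pytest.approx(3.0) for v in ft.nc_centrality(k4()).values())


@pytest.mark.parametrize("seed,n,p", [(0, 12, 0.3), (1, 20, 0.15), (2, 25, 0.1)])
def test_centralities_match_brute_force(seed, n, p):
    net = random_network(n, p, seed)
    pairs = [
        (ft.degree_centrality, oracles.degree_oracle),
        (ft.betweenness_centrality, oracles.betweenness_oracle),
        (ft.closeness_centrality, oracles.closeness_oracle),
        (ft.subgraph_centrality, oracles.subgraph_oracle),
        (ft.eigenvector_centrality, oracles.eigenvector_oracle),
        (ft.information_centrality, oracles.information_oracle),
        (ft.nc_centrality, oracles.nc_oracle),
    ]
    for impl, oracle in pairs:
        got, want = impl(net), oracle(net)
        for v in net.nodes:
            assert got[v] == pytest.approx(want[v], abs=1e-8), (impl.__name__, v)


class TestEcc:
    def test_triangle_edge_is_one(self):
        assert ft.edge_clustering_coefficient(k3(), "A", "B") == 1.0

    def test_star_and_pendant_edges_are_zero(self):
        assert ft.edge_clustering_coefficient(star3(), "S", "L1") == 0.0
        assert ft.edge_clustering_coefficient(path3(), "A", "B") == 0.0

    def test_absent_edge_errors(self):
        with pytest.raises(ValueError):
            ft.edge_clustering_coefficient(path3(), "A", "C")

    @pytest.mark.parametrize("seed", range(4))
    def test_symmetric_and_bounded(self, seed):
        net = random_network(15, 0.3, seed)
        for e, val in ft.edge_clustering_coefficients(net).items():
            u, v = tuple(e)
            assert 0.0 <= val <= 1.0
            assert ft.edge_clustering_coefficient(net, u, v) == \
                ft.edge_clustering_coefficient(net, v, u) == pytest.approx(val)


class TestCoexpression:
    def test_identical_and_negated_profiles(self):
        expr = pd.DataFrame([[1, 2, 3], [1, 2, 3], [-1, -2, -3]],
                            index=["A", "B", "C"], columns=["s1", "s2", "s3"])
        assert ft.pearson_coexpression(expr, "A", "B") == pytest.approx(1.0)
        assert ft.pearson_coexpression(expr, "A", "C") == pytest.approx(-1.0)

    def test_textbook_formula(self):
        x, y = np.array([1, 2, 3, 4.0]), np.array([2, 4, 6, 9.0])
        n = 4
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = math.sqrt(n * (x * x).sum() - x.sum() ** 2) * \
            math.sqrt(n * (y * y).sum() - y.sum() ** 2)
        expr = pd.DataFrame([x, y], index=["A", "B"])
        assert ft.pearson_coexpression(expr, "A", "B") == pytest.approx(num / den)

    def test_missing_or_constant_profile_gives_zero(self):
        expr = pd.DataFrame([[1, 1, 1], [1, 2, 3]], index=["A", "B"])
        assert ft.pearson_coexpression(expr, "A", "B") == 0.0
        assert ft.pearson_coexpression(expr, "B", "Z") == 0.0


def _const_expr(nodes, value_rows):
    return pd.DataFrame(value_rows, index=nodes,
                        columns=[f"s{i}" for i in range(len(value_rows[0]))])


class TestComposites:
    def test_pec_k3_identical_profiles(self):
        expr = _const_expr(["A", "B", "C"], [[1, 2, 3, 4]] * 3)
        pec = ft.pec_score(k3(), expr)
        assert all(v == pytest.approx(2.0) for v in pec.values())

    def test_pec_without_expression_is_zero(self):
        pec = ft.pec_score(k3(), pd.DataFrame())
        assert all(v == 0.0 for v in pec.values())

    def test_pec_floors_negative_correlation(self):
        expr = _const_expr(["A", "B", "C"], [[1, 2, 3], [-1, -2, -3], [1, 2, 3]])
        pec = ft.pec_score(k3(), expr)
        assert pec["A"] == pytest.approx(1.0)  # only the A-C edge contributes

    def test_wdc_limits(self):
        expr = _const_expr(["A", "B", "C"], [[1, 2, 3, 4]] * 3)
        net = k3()
        assert ft.wdc_score(net, expr, lam=1.0) == pytest.approx(ft.nc_centrality(net))
        assert ft.wdc_score(net, expr, lam=0.0) == pytest.approx(ft.degree_centrality(net))
        assert all(v == pytest.approx(2.0) for v in ft.wdc_score(net, expr, lam=0.5).values())
        with pytest.raises(ValueError):
            ft.wdc_score(net, expr, lam=1.5)

    def test_ion_alpha_zero_is_normalized_orthology(self):
        orth = pd.Series({"A": 4.0, "B": 2.0, "C": 0.0})
        ion = ft.ion_score(path3(), orth, alpha=0.0)
        assert ion == pytest.approx({"A": 1.0, "B": 0.5, "C": 0.0})

    def test_ion_symmetric_graph_equal_scores(self):
        orth = pd.Series({v: 1.0 for v in "ABCD"})
        ion = ft.ion_score(k4(), orth, alpha=0.85)
        assert len(set(round(v, 10) for v in ion.values())) == 1

    def test_ion_path_matches_long_run_iteration(self):
        net = path3()
        orth = pd.Series({"A": 1.0, "B": 0.0, "C": 0.0})
        got = ft.ion_score(net, orth, alpha=0.5, tol=1e-15, max_iter=2000)
        # independent oracle: naive 1000-step iteration over explicit sums
        alpha, o = 0.5, {"A": 1.0, "B": 0.0, "C": 0.0}
        nbrs = {"A": ["B"], "B": ["A", "C"], "C": ["B"]}
        s = dict(o)
        for _ in range(1000):
            s = {i: (1 - alpha) * o[i]
                 + alpha * sum(s[j] / len(nbrs[j]) for j in nbrs[i]) for i in s}
        for v in "ABC":
            assert got[v] == pytest.approx(s[v], abs=1e-9)

    def test_ion_relabeling_equivariance(self):
        net = random_network(15, 0.25, seed=3)
        rng = np.random.default_rng(0)
        orth = pd.Series(rng.uniform(0, 5, 15), index=sorted(net.nodes))
        ion = ft.ion_score(net, orth)
        perm = {v: f"Q{v}" for v in net.nodes}
        import networkx as nx
        net2 = InteractionNetwork(nx.relabel_nodes(net.graph, perm))
        orth2 = orth.rename(index=perm)
        ion2 = ft.ion_score(net2, orth2)
        for v in net.nodes:
            assert ion2[perm[v]] == pytest.approx(ion[v], abs=1e-12)


class TestAssembly:
    def test_max_division(self):
        raw = pd.DataFrame({"DC": [2.0, 4.0, 8.0]}, index=["A", "B", "C"])
        assert list(ft.normalize_features(raw)["DC"]) == [0.25, 0.5, 1.0]

    def test_all_zero_column_left_as_zero(self, caplog):
        raw = pd.DataFrame({"X": [0.0, 0.0]}, index=["A", "B"])
        with caplog.at_level("WARNING"):
            out = ft.normalize_features(raw)
        assert (out["X"] == 0).all()
        assert any("constant zero" in r.message for r in caplog.records)

    def test_fixture_table_is_normalized(self, dataset):
        table = dataset.features
        assert ((table >= -1) & (table <= 1)).all().all()
        assert not table.isna().any().any()
        for col in ft.TOPOLOGY_FEATURES + ft.COMPOSITE_FEATURES:
            if table[col].abs().max() > 0:
                assert table[col].abs().max() == pytest.approx(1.0)
        for comp in ft.FeatureConfig().compartments:
            assert set(table[comp].unique()) <= {0.0, 1.0}
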