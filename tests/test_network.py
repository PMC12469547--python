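from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from metabloc.network import (
    Network,
    betweenness_centrality,
    differential_network,
    edge_pvalues,
    full_network,
    minimal_network,
    select_hub_blocks,
    shrinkage_partial_correlation,
)


def _net(nodes, pairs, pcors=None, ps=None):
    rows = []
    for i, (a, b) in enumerate(pairs):
        rows.append(
            (a, b, pcors[i] if pcors else 0.5, ps[i] if ps else 0.01)
        )
    return Network(nodes=list(nodes), edges=pd.DataFrame(rows, columns=["node_a", "node_b", "pcor", "p"]))


class TestShrinkagePartialCorrelation:
    def test_matches_inverse_covariance_at_zero_shrinkage(self, rng):
        """lambda = 0 reproduces the closed-form inverse-correlation pcor."""
        x = rng.normal(size=(50, 4)) @ rng.normal(size=(4, 4))
        df = pd.DataFrame(x, columns=list("abcd"))
        pcor, lam = shrinkage_partial_correlation(df, shrinkage=0.0)
        r = np.corrcoef(x.T)
        omega = np.linalg.inv(r)
        d = np.sqrt(np.diag(omega))
        expected = -omega / np.outer(d, d)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(pcor.to_numpy(), expected, atol=1e-10)
        assert lam == 0.0

    def test_full_shrinkage_zeroes_offdiagonals(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 5)))
        pcor, _ = shrinkage_partial_correlation(df, shrinkage=1.0)
        off = pcor.to_numpy() - np.eye(5)
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_chain_conditional_independence(self, rng):
        """X -> Y -> Z with rho = 0.8: pcor(X, Z | Y) vanishes."""
        n = 2000
        x = rng.normal(size=n)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.normal(size=n)
        z = 0.8 * y + np.sqrt(1 - 0.64) * rng.normal(size=n)
        pcor, _ = shrinkage_partial_correlation(
            pd.DataFrame({"x": x, "y": y, "z": z}), shrinkage=0.0
        )
        assert abs(pcor.loc["x", "z"]) < 0.05
        assert pcor.loc["x", "y"] > 0.5

    def test_analytic_lambda_in_unit_interval(self, rng):
        df = pd.DataFrame(rng.normal(size=(12, 8)))
        _, lam = shrinkage_partial_correlation(df)
        assert 0.0 <= lam <= 1.0

    def test_minimum_samples_enforced(self, rng):
        with pytest.raises(ValueError, match="5 samples"):
            shrinkage_partial_correlation(pd.DataFrame(rng.normal(size=(4, 3))))


class TestEdgePvalues:
    def test_zero_pcor_gives_p_one(self):
        pcor = pd.DataFrame(np.eye(3), columns=list("abc"), index=list("abc"))
        edges = edge_pvalues(pcor, n_samples=50)
        np.testing.assert_allclose(edges["p"], 1.0)

    def test_monotone_in_magnitude(self):
        labels = list("abcd")
        m = np.eye(4)
        vals = [0.1, -0.3, 0.5, 0.7, -0.2, 0.05]
        for (i, j), v in zip(combinations(range(4), 2), vals):
            m[i, j] = m[j, i] = v
        edges = edge_pvalues(pd.DataFrame(m, columns=labels, index=labels), n_samples=40)
        order = edges.sort_values("p")
        mags = order["pcor"].abs().to_numpy()
        assert (np.diff(mags) <= 1e-12).all()

    def test_unit_pcor_gives_p_zero(self):
        m = np.array([[1, 1.0, 0], [1.0, 1, 0], [0, 0, 1.0]])
        edges = edge_pvalues(pd.DataFrame(m, columns=list("abc"), index=list("abc")), 30)
        assert edges.loc[(edges.node_a == "a") & (edges.node_b == "b"), "p"].iloc[0] == 0.0

    def test_null_pvalues_uniform(self, rng):
        """Independent block scores give ~uniform edge p-values (KS < 0.1)."""
        from scipy import stats

        ps = []
        while len(ps) < 2000:
            df = pd.DataFrame(rng.normal(size=(96, 14)))
            net = full_network(df, shrinkage=0.0)
            ps.extend(net.edges["p"].tolist())
        ks = stats.kstest(np.asarray(ps[:2000]), "uniform").statistic
        assert ks < 0.1


class TestMinimalNetwork:
    def test_two_nodes_keep_their_single_edge(self):
        net = _net("ab", [("a", "b")], ps=[0.9])
        mn = minimal_network(net)
        assert len(mn.edges) == 1

    def test_hand_enumerated_toy(self):
        """{AB: .001, CD: .002} covers all four nodes: exactly those retained."""
        pairs = [("A", "B"), ("C", "D"), ("A", "C"), ("B", "D"), ("A", "D"), ("B", "C")]
        ps = [0.001, 0.002, 0.01, 0.2, 0.5, 0.9]
        mn = minimal_network(_net("ABCD", pairs, ps=ps))
        assert mn.edge_set == {frozenset(("A", "B")), frozenset(("C", "D"))}

    def test_prefix_extends_until_coverage(self):
        pairs = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]
        ps = [0.001, 0.002, 0.9, 0.01, 0.05, 0.5]
        mn = minimal_network(_net("ABCD", pairs, ps=ps))
        # AB, AC then BC (no new node), BD finally covers D
        assert mn.edge_set == {
            frozenset(("A", "B")),
            frozenset(("A", "C")),
            frozenset(("B", "C")),
            frozenset(("B", "D")),
        }

    def test_star_topology_recovered(self, rng):
        """A hub driving k leaves keeps exactly the hub-leaf edges."""
        n = 400
        hub = rng.normal(size=n)
        cols = {"hub": hub}
        for i in range(5):
            cols[f"leaf{i}"] = 0.8 * hub + 0.6 * rng.normal(size=n)
        mn = minimal_network(full_network(pd.DataFrame(cols)))
        expected = {frozenset(("hub", f"leaf{i}")) for i in range(5)}
        assert mn.edge_set == expected

    def test_minimality_certificate(self, rng):
        """Dropping the last-ranked retained edge isolates at least one node."""
        df = pd.DataFrame(rng.normal(size=(40, 8)))
        mn = minimal_network(full_network(df))
        g = nx.Graph()
        g.add_nodes_from(mn.nodes)
        for _, row in mn.edges.iloc[:-1].iterrows():
            g.add_edge(row["node_a"], row["node_b"])
        assert any(g.degree(n) == 0 for n in g.nodes)

    def test_connectivity_variant_connects(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 8)))
        mn = minimal_network(full_network(df), criterion="connectivity")
        assert nx.is_connected(mn.to_networkx())


class TestDifferentialNetwork:
    def test_identical_networks_cancel(self):
        net = _net("abc", [("a", "b"), ("b", "c")])
        diff = differential_network(net, net)
        assert len(diff.edges) == 0
        assert set(diff.nodes) == {"a", "b", "c"}

    def test_disjoint_edges_pass_through(self):
        prem = _net("abcd", [("a", "b"), ("c", "d")])
        term = _net("abcd", [("a", "c")])
        diff = differential_network(prem, term)
        assert diff.edge_set == prem.edge_set

    def test_overlap_set_algebra(self):
        prem = _net("abcd", [("a", "b"), ("b", "c")])
        term = _net("abcd", [("b", "c"), ("c", "d")])
        diff = differential_network(prem, term)
        assert diff.edge_set == {frozenset(("a", "b"))}

    def test_node_set_mismatch_rejected(self):
        with pytest.raises(ValueError, match="node"):
            differential_network(_net("ab", [("a", "b")]), _net("ac", [("a", "c")]))

    def test_label_swap_symmetry(self):
        prem = _net("abcd", [("a", "b"), ("b", "c")])
        term = _net("abcd", [("b", "c"), ("c", "d")])
        d1 = differential_network(prem, term)
        d2 = differential_network(term, prem)
        assert d1.edge_set == {frozenset(("a", "b"))}
        assert d2.edge_set == {frozenset(("c", "d"))}


def _brute_force_betweenness(g):
    """Count geodesic pass-throughs by explicit path enumeration."""
    bc = {n: 0.0 for n in g.nodes}
    for s, t in combinations(g.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for node in g.nodes:
            if node in (s, t):
                continue
            through = sum(node in p for p in paths)
            bc[node] += through / len(paths)
    return bc


class TestBetweenness:
    def test_path_center(self):
        net = _net("abc", [("a", "b"), ("b", "c")])
        bc = betweenness_centrality(net)
        assert bc["b"] == 1.0 and bc["a"] == 0.0 and bc["c"] == 0.0

    def test_complete_graph_all_zero(self):
        pairs = list(combinations("abcd", 2))
        net = _net("abcd", pairs)
        assert (betweenness_centrality(net) == 0).all()

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(30):
            g = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(2**31)))
            mapping = {i: f"n{i}" for i in g.nodes}
            g = nx.relabel_nodes(g, mapping)
            rows = [(a, b, 0.5, 0.01) for a, b in g.edges]
            net = Network(
                nodes=list(g.nodes),
                edges=pd.DataFrame(rows, columns=["node_a", "node_b", "pcor", "p"]),
            )
            bc = betweenness_centrality(net)
            expected = _brute_force_betweenness(g)
            for node in g.nodes:
                assert bc[node] == pytest.approx(expected[node], abs=1e-9)


class TestHubSelection:
    def test_architectural_hub_selected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            leaves = [f"l{i}" for i in range(11)]
            pairs = [("hub", l) for l in leaves]
            net = _net(["hub"] + leaves, pairs)
            diff = Network(nodes=net.nodes, edges=net.edges, kind="differential")
            bc = betweenness_centrality(diff)
            hubs, _ = select_hub_blocks(bc)
            hits += hubs == ["hub"]
        assert hits >= 18

    def test_edgeless_network_selects_nothing(self):
        net = Network(
            nodes=[f"n{i}" for i in range(12)],
            edges=pd.DataFrame(columns=["node_a", "node_b", "pcor", "p"]),
            kind="differential",
        )
        bc = betweenness_centrality(net)
        hubs, thr = select_hub_blocks(bc)
        assert hubs == [] and np.isinf(thr)

    def test_few_nodes_need_manual_threshold(self):
        bc = pd.Series([0.0, 1.0, 2.0], index=list("abc"))
        with pytest.raises(ValueError, match="manual"):
            select_hub_blocks(bc)
        hubs, _ = select_hub_blocks(bc, threshold=1.5)
        assert hubs == ["c"]
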