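"""Group-wise shrinkage partial-correlation networks over block superscores.

For each group, the block-superscore correlation matrix is shrunk
toward the identity with the analytic Schafer-Strimmer/Ledoit-Wolf
weight, inverted, and converted to partial correlations (a Gaussian
graphical model).  Each edge gets a two-sided p-value from the exact
null density of sample partial correlations.  The minimal network is
the smallest p-ordered edge prefix in which every node keeps at least
one edge; subtracting the Term minimal network from the Prem one leaves
the Prem-specific (differential) network, whose hubs are ranked by
unweighted Brandes betweenness centrality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .latent import normality_threshold

__all__ = [
    "Network",
    "shrinkage_partial_correlation",
    "edge_pvalues",
    "full_network",
    "minimal_network",
    "differential_network",
    "betweenness_centrality",
    "select_hub_blocks",
]

EDGE_COLUMNS = ["node_a", "node_b", "pcor", "p"]


@dataclass
class Network:
    """An undirected network over block labels.

    ``edges`` has columns node_a, node_b (node_a < node_b), pcor, p;
    each unordered pair appears at most once, no self-edges.
    """

    nodes: list[str]
    edges: pd.DataFrame
    kind: str = "full"
    betweenness: pd.Series | None = None

    def __post_init__(self) -> None:
        e = self.edges
        if len(e):
            if (e["node_a"] == e["node_b"]).any():
                raise ValueError("self-edges are not allowed")
            pairs = list(zip(e["node_a"], e["node_b"]))
            if len(set(map(frozenset, pairs))) != len(pairs):
                raise ValueError("duplicate unordered edge")

    @property
    def edge_set(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b in zip(self.edges["node_a"], self.edges["node_b"])}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, row in self.edges.iterrows():
            g.add_edge(row["node_a"], row["node_b"], pcor=row["pcor"], p=row["p"])
        return g


def shrinkage_partial_correlation(
    scores: pd.DataFrame, shrinkage: float | None = None
) -> tuple[pd.DataFrame, float]:
    """Partial correlations from a shrunken correlation matrix.

    The sample correlation matrix R is replaced by
    R* = lambda I + (1 - lambda) R with the analytic optimal
    lambda = sum Var(r_ij) / sum r_ij^2 (clipped to [0, 1]); partial
    correlations follow from the inverse: pcor_ij = -O_ij / sqrt(O_ii O_jj).
    Pass ``shrinkage`` to force a specific lambda (0 disables shrinkage).
    """
    x = scores.to_numpy(dtype=float)
    n, g = x.shape
    if n < 5:
        raise ValueError("need at least 5 samples per group")
    if g < 3:
        raise ValueError("need at least 3 blocks")
    sds = x.std(axis=0, ddof=1)
    if (sds <= 0).any():
        raise ValueError("constant block score column; cannot correlate")
    z = (x - x.mean(axis=0)) / sds
    w_bar = z.T @ z / n                      # mean of w_kij = z_ki z_kj
    r = w_bar * n / (n - 1)

    if shrinkage is None:
        # Var-hat(r_ij) = n / (n-1)^3 * sum_k (w_kij - w_bar_ij)^2
        sq = (z**2).T @ (z**2) / n           # mean of w_kij^2
        var_w = sq - w_bar**2
        var_r = n / (n - 1) ** 3 * n * var_w
        iu = np.triu_indices(g, k=1)
        denom = float(np.sum(r[iu] ** 2))
        lam = 1.0 if denom <= 0 else float(np.clip(np.sum(var_r[iu]) / denom, 0.0, 1.0))
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")

    r_star = lam * np.eye(g) + (1.0 - lam) * r
    np.fill_diagonal(r_star, 1.0)
    try:
        omega = np.linalg.inv(r_star)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "shrunken correlation matrix is singular; set a positive shrinkage floor"
        ) from exc
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    labels = list(scores.columns)
    return pd.DataFrame(pcor, index=labels, columns=labels), lam


def edge_pvalues(pcor: pd.DataFrame, n_samples: int) -> pd.DataFrame:
    """Two-sided edge p-values from the exact null of partial correlations.

    Under the null a sample partial correlation r given G - 2 other
    variables has density f0(r; kappa) prop. (1 - r^2)^((kappa - 3)/2)
    with kappa = n - (G - 2) - 1 degrees of freedom (floored at 3);
    equivalently r^2 ~ Beta(1/2, (kappa - 1)/2), so
    p = P(R^2 >= r^2) = Beta.sf(r^2).
    """
    g = pcor.shape[0]
    kappa = max(3, n_samples - (g - 2) - 1)
    labels = list(pcor.columns)
    rows = []
    for i in range(g):
        for j in range(i + 1, g):
            r = float(pcor.iloc[i, j])
            if abs(r) >= 1.0:
                p = 0.0
            else:
                p = float(stats.beta.sf(r**2, 0.5, (kappa - 1) / 2.0))
            rows.append((labels[i], labels[j], r, p))
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def full_network(scores: pd.DataFrame, shrinkage: float | None = None) -> Network:
    """All-pairs partial-correlation network for one group's superscores."""
    pcor, _lam = shrinkage_partial_correlation(scores, shrinkage=shrinkage)
    edges = edge_pvalues(pcor, n_samples=len(scores))
    return Network(nodes=list(scores.columns), edges=edges, kind="full")


def _edge_order(edges: pd.DataFrame) -> pd.DataFrame:
    """Deterministic edge ordering: p asc, |pcor| desc, lexicographic pair."""
    e = edges.copy()
    e["_abs"] = -e["pcor"].abs()
    e = e.sort_values(["p", "_abs", "node_a", "node_b"], kind="mergesort")
    return e.drop(columns="_abs")


def minimal_network(net: Network, criterion: str = "coverage") -> Network:
    """Smallest p-ordered edge prefix keeping every node attached.

    ``criterion='coverage'`` (default) stops once every node is incident
    to at least one retained edge; ``'connectivity'`` stops once the
    graph is connected.  Nodes whose best edge has p = 1 still get it:
    inclusion of the whole node set is mandatory.
    """
    if criterion not in ("coverage", "connectivity"):
        raise ValueError("criterion must be 'coverage' or 'connectivity'")
    ordered = _edge_order(net.edges)
    kept_rows = []
    covered: set[str] = set()
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    target = set(net.nodes)
    done = False
    for _, row in ordered.iterrows():
        if done:
            break
        kept_rows.append(row)
        covered.update((row["node_a"], row["node_b"]))
        g.add_edge(row["node_a"], row["node_b"])
        if criterion == "coverage":
            done = covered >= target
        else:
            done = nx.is_connected(g)
    if not done:
        raise ValueError("edge list cannot satisfy the minimality criterion")
    edges = pd.DataFrame(kept_rows, columns=EDGE_COLUMNS).reset_index(drop=True)
    return Network(nodes=list(net.nodes), edges=edges, kind="minimal")


def differential_network(prem: Network, term: Network) -> Network:
    """Prem-specific network: edges of prem not present in term.

    Attributes come from the prem network; isolated nodes are kept.
    """
    if set(prem.nodes) != set(term.nodes):
        raise ValueError("node sets differ between the two networks")
    term_edges = term.edge_set
    keep = [
        frozenset((a, b)) not in term_edges
        for a, b in zip(prem.edges["node_a"], prem.edges["node_b"])
    ]
    edges = prem.edges.loc[keep].reset_index(drop=True)
    net = Network(nodes=list(prem.nodes), edges=edges, kind="differential")
    net.betweenness = betweenness_centrality(net)
    return net


def betweenness_centrality(net: Network) -> pd.Series:
    """Unweighted shortest-path betweenness (Brandes), unnormalized.

    Each unordered pair is counted once; pairs in different components
    contribute nothing.
    """
    g = net.to_networkx()
    bc = nx.betweenness_centrality(g, normalized=False)
    return pd.Series(bc, name="betweenness").loc[net.nodes]


def select_hub_blocks(
    betweenness: pd.Series,
    threshold: float | None = None,
    k_sd: float = 2.0,
) -> tuple[list[str], float]:
    """Hub blocks: nodes whose betweenness clears the normality-plot threshold.

    Returns (hubs in descending betweenness, threshold).  With fewer
    than 10 nodes a manual ``threshold`` is required.
    """
    if threshold is None:
        if len(betweenness) < 10:
            raise ValueError("fewer than 10 nodes: pass a manual threshold")
        thr = normality_threshold(betweenness.to_numpy(), k_sd=k_sd)
    else:
        thr = float(threshold)
    hubs = betweenness[betweenness >= thr].sort_values(ascending=False)
    return list(hubs.index), thr
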