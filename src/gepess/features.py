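"""Topological and biological features of proteins in a PPI network.

Seven centralities (DC, BC, CC, SC, EC, IC, NC), the pairwise co-expression
correlation (PCC), and three composite essentiality scores:

* **PeC** — sum over neighbours of edge clustering coefficient times
  co-expression, rewarding proteins embedded in densely interacting,
  co-expressed neighbourhoods (essential proteins cluster in complexes
  whose members are co-expressed).
* **WDC** — a weighted sum ``lambda * ECC + (1 - lambda) * PCC`` over
  incident edges, blending topology with expression.
* **ION** — an orthology-seeded propagation on the ECC-weighted network:
  conserved proteins transfer score to their interaction partners,
  capturing the observation that essential proteins are both conserved and
  interconnected.

``assemble_feature_table`` combines everything with the subcellular
localization indicators into one normalized table whose values lie in
[-1, 1] (each column divided by its maximum absolute value).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import DEFAULT_COMPARTMENTS, InteractionNetwork

logger = logging.getLogger(__name__)

TOPOLOGY_FEATURES = ("DC", "BC", "CC", "SC", "EC", "IC", "NC")
COMPOSITE_FEATURES = ("PeC", "WDC", "ION")


@dataclass
class FeatureConfig:
    """Tunable parameters of the composite features.

    wdc_lambda : topology-vs-expression blend of WDC, in [0, 1].
    ion_alpha : propagation strength of ION, in [0, 1).
    ion_tol, ion_max_iter : fixed-point stopping rule for ION.
    pec_floor_negative / wdc_floor_negative : whether negative
        co-expression correlations are floored at 0 (PeC: yes, WDC: no).
    """

    wdc_lambda: float = 0.5
    ion_alpha: float = 0.85
    ion_tol: float = 1e-6
    ion_max_iter: int = 100
    pec_floor_negative: bool = True
    wdc_floor_negative: bool = False
    compartments: tuple[str, ...] = DEFAULT_COMPARTMENTS
    ec_tol: float = 1e-12
    ec_max_iter: int = 10_000


# ---------------------------------------------------------------------------
# centralities


def degree_centrality(network: InteractionNetwork) -> dict[str, float]:
    """DC(v) = number of neighbours of v."""
    return {v: float(d) for v, d in network.graph.degree()}


def betweenness_centrality(network: InteractionNetwork) -> dict[str, float]:
    """Unnormalized shortest-path betweenness over unordered pairs."""
    return {v: float(b) for v, b in
            nx.betweenness_centrality(network.graph, normalized=False).items()}


def closeness_centrality(network: InteractionNetwork) -> dict[str, float]:
    """Component-restricted closeness: (n_comp - 1) / sum of distances
    within v's connected component; isolated nodes score 0."""
    return {v: float(c) for v, c in
            nx.closeness_centrality(network.graph, wf_improved=False).items()}


def subgraph_centrality(network: InteractionNetwork) -> dict[str, float]:
    """SC(v) = [exp(A)]_vv, the weighted count of closed walks at v."""
    g = network.graph
    sc: dict[str, float] = {}
    # networkx's implementation rejects graphs with isolated pieces of size
    # one only implicitly; handle components ourselves for robustness.
    for comp in nx.connected_components(g):
        if len(comp) == 1:
            sc[next(iter(comp))] = 1.0
            continue
        sub = g.subgraph(comp)
        sc.update({v: float(s) for v, s in nx.subgraph_centrality(sub).items()})
    return sc


def eigenvector_centrality(network: InteractionNetwork,
                           tol: float = 1e-12,
                           max_iter: int = 10_000) -> dict[str, float]:
    """Nonnegative principal eigenvector of the largest connected
    component's adjacency matrix, unit Euclidean norm; nodes outside the
    largest component score 0.

    Computed by power iteration; raises if it fails to converge.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("eigenvector centrality of an empty network")
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    comp = sorted(comps[0])
    result = {v: 0.0 for v in g.nodes}
    if len(comp) == 1:
        result[comp[0]] = 1.0
        return result
    a = nx.to_numpy_array(g, nodelist=comp)
    x = np.full(len(comp), 1.0 / np.sqrt(len(comp)))
    for _ in range(max_iter):
        # shifted iteration (A + I): same eigenvectors, but the dominant
        # eigenvalue is strictly largest in magnitude even on bipartite
        # components, so the iteration cannot oscillate
        y = a @ x + x
        norm = np.linalg.norm(y)
        if norm == 0:  # cannot happen for a connected component with an edge
            raise ValueError("eigenvector iteration collapsed to zero")
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    else:
        raise RuntimeError(f"eigenvector centrality did not converge in {max_iter} iterations")
    x = np.abs(x)  # Perron vector of a connected component is positive
    x /= np.linalg.norm(x)
    for v, val in zip(comp, x):
        result[v] = float(val)
    return result


def information_centrality(network: InteractionNetwork) -> dict[str, float]:
    """Current-flow (information) centrality per connected component.

    With C = (L + J)^-1 on a component of size n (L the Laplacian, J the
    all-ones matrix), pairwise information is I_ij = 1 / (c_ii + c_jj -
    2 c_ij) and IC(i) = n / sum_j (1 / I_ij), taking 1 / I_ii = 0.
    Isolated nodes score 0.
    """
    g = network.graph
    ic: dict[str, float] = {}
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        n = len(comp)
        if n == 1:
            ic[comp[0]] = 0.0
            continue
        lap = nx.laplacian_matrix(g.subgraph(comp), nodelist=comp).toarray().astype(float)
        c = np.linalg.inv(lap + np.ones((n, n)))
        d = np.diag(c)
        r = d[:, None] + d[None, :] - 2.0 * c  # pairwise effective resistances
        np.fill_diagonal(r, 0.0)
        totals = r.sum(axis=1)
        for v, t in zip(comp, totals):
            ic[v] = float(n / t)
    return ic


# ---------------------------------------------------------------------------
# edge clustering coefficient and NC


def edge_clustering_coefficient(network: InteractionNetwork, u: str, v: str) -> float:
    """ECC(u, v) = common neighbours / min(d_u - 1, d_v - 1).

    A pendant edge (either endpoint of degree 1) participates in no
    triangle, so its ECC is 0 by convention.
    """
    g = network.graph
    if not g.has_edge(u, v):
        raise ValueError(f"edge ({u!r}, {v!r}) not in network")
    denom = min(g.degree(u) - 1, g.degree(v) - 1)
    if denom <= 0:
        return 0.0
    z = len(set(g[u]) & set(g[v]))
    return z / denom


def edge_clustering_coefficients(network: InteractionNetwork) -> dict[frozenset, float]:
    """ECC for every edge, keyed by frozenset endpoint pair."""
    g = network.graph
    adj = {v: set(g[v]) for v in g.nodes}
    deg = dict(g.degree())
    out = {}
    for u, v in g.edges:
        denom = min(deg[u] - 1, deg[v] - 1)
        out[frozenset((u, v))] = (len(adj[u] & adj[v]) / denom) if denom > 0 else 0.0
    return out


def nc_centrality(network: InteractionNetwork) -> dict[str, float]:
    """NC(v) = sum of ECC over v's incident edges."""
    ecc = edge_clustering_coefficients(network)
    nc = {v: 0.0 for v in network.graph.nodes}
    for edge, val in ecc.items():
        for v in edge:
            nc[v] += val
    return nc


# ---------------------------------------------------------------------------
# co-expression


def pearson_coexpression(expression: pd.DataFrame, u: str, v: str) -> float:
    """Pearson correlation of two proteins' expression profiles.

    Returns 0 when either protein has no expression row or a constant
    profile (zero variance): a neutral contribution.
    """
    if u not in expression.index or v not in expression.index:
        return 0.0
    x = expression.loc[u].to_numpy(dtype=float)
    y = expression.loc[v].to_numpy(dtype=float)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _edge_pcc(network: InteractionNetwork, expression: pd.DataFrame) -> dict[frozenset, float]:
    g = network.graph
    covered = expression.index.intersection(list(g.nodes))
    if len(covered) == 0 or expression.shape[1] == 0:
        return {frozenset((u, v)): 0.0 for u, v in g.edges}
    mat = expression.loc[covered].to_numpy(dtype=float)
    idx = {p: i for i, p in enumerate(covered)}
    sd = mat.std(axis=1)
    centered = mat - mat.mean(axis=1, keepdims=True)
    out = {}
    for u, v in g.edges:
        iu, iv = idx.get(u), idx.get(v)
        if iu is None or iv is None or sd[iu] == 0.0 or sd[iv] == 0.0:
            out[frozenset((u, v))] = 0.0
        else:
            num = float(centered[iu] @ centered[iv])
            out[frozenset((u, v))] = num / (mat.shape[1] * sd[iu] * sd[iv])
    return out


def pec_score(network: InteractionNetwork, expression: pd.DataFrame,
              floor_negative: bool = True) -> dict[str, float]:
    """PeC(i) = sum over neighbours j of ECC(i,j) * PCC(i,j).

    Negative correlations are floored at 0 by default, so anti-correlated
    neighbours contribute nothing rather than subtracting.
    """
    ecc = edge_clustering_coefficients(network)
    pcc = _edge_pcc(network, expression)
    pec = {v: 0.0 for v in network.graph.nodes}
    for edge in ecc:
        p = pcc[edge]
        if floor_negative:
            p = max(p, 0.0)
        w = ecc[edge] * p
        for v in edge:
            pec[v] += w
    return pec


def wdc_score(network: InteractionNetwork, expression: pd.DataFrame,
              lam: float = 0.5, floor_negative: bool = False) -> dict[str, float]:
    """WDC(i) = sum over neighbours j of lam*ECC(i,j) + (1-lam)*PCC(i,j).

    lam = 1 recovers NC exactly; lam = 0 with all-unit correlations
    recovers DC. The signed correlation is kept by default.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    ecc = edge_clustering_coefficients(network)
    pcc = _edge_pcc(network, expression)
    wdc = {v: 0.0 for v in network.graph.nodes}
    for edge in ecc:
        p = pcc[edge]
        if floor_negative:
            p = max(p, 0.0)
        w = lam * ecc[edge] + (1.0 - lam) * p
        for v in edge:
            wdc[v] += w
    return wdc


def ion_score(network: InteractionNetwork, orthology: pd.Series,
              alpha: float = 0.85, tol: float = 1e-6,
              max_iter: int = 100) -> dict[str, float]:
    """Orthology-seeded iterative score on the ECC-weighted network.

    Fixed point of ``S(i) = (1 - alpha) * O(i) + alpha * sum_{j in N(i)}
    W(j, i) * S(j)`` where O is the conservation score max-normalized to
    [0, 1] and ``W(j, i) = ECC(j, i) / sum_k ECC(j, k)`` (uniform ``1/d_j``
    when all of j's incident ECCs vanish). Iterates from S = O until the
    L1 change drops below ``tol``; warns and returns the last iterate if
    ``max_iter`` is reached. Since each row of W sums to 1, the map is an
    alpha-contraction in L1 and convergence is geometric.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    g = network.graph
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    o = np.array([float(orthology.get(v, 0.0)) for v in nodes])
    if o.max() > 0:
        o = o / o.max()
    ecc = edge_clustering_coefficients(network)
    # row-stochastic transfer matrix W (rows: source j, cols: target i)
    n = len(nodes)
    w = np.zeros((n, n))
    for j in nodes:
        nbrs = list(g[j])
        if not nbrs:
            continue
        weights = np.array([ecc[frozenset((j, k))] for k in nbrs])
        total = weights.sum()
        if total == 0.0:
            weights = np.full(len(nbrs), 1.0 / len(nbrs))
        else:
            weights = weights / total
        jj = idx[j]
        for k, wt in zip(nbrs, weights):
            w[jj, idx[k]] = wt
    s = o.copy()
    for _ in range(max_iter):
        s_new = (1.0 - alpha) * o + alpha * (w.T @ s)
        if np.abs(s_new - s).sum() < tol:
            s = s_new
            break
        s = s_new
    else:
        warnings.warn(f"ION iteration did not converge within {max_iter} iterations; "
                      "returning last iterate", RuntimeWarning, stacklevel=2)
    return {v: float(s[idx[v]]) for v in nodes}


# ---------------------------------------------------------------------------
# assembly


def normalize_features(raw: pd.DataFrame) -> pd.DataFrame:
    """Divide each column by its maximum absolute value so every feature
    lies in [-1, 1]; all-zero columns are left as zeros with a warning."""
    out = raw.copy()
    for col in out.columns:
        m = out[col].abs().max()
        if m == 0 or not np.isfinite(m):
            logger.warning("normalize_features: column %r is constant zero", col)
            out[col] = 0.0
        else:
            out[col] = out[col] / m
    return out


def assemble_feature_table(network: InteractionNetwork,
                           expression: pd.DataFrame | None = None,
                           localization: pd.DataFrame | None = None,
                           orthology: pd.Series | None = None,
                           config: FeatureConfig | None = None) -> pd.DataFrame:
    """Compute every feature and return the normalized table.

    Rows: sorted protein IDs of the network. Columns: DC, BC, CC, SC, EC,
    IC, NC, PeC, WDC, ION and one 0/1 indicator per compartment. Absent
    biological data contributes 0 before normalization.
    """
    cfg = config or FeatureConfig()
    nodes = sorted(network.graph.nodes)
    if not nodes:
        raise ValueError("cannot featurize an empty network")
    expr = expression if expression is not None else pd.DataFrame(index=pd.Index([], dtype=object))
    orth = orthology if orthology is not None else pd.Series(dtype=float)

    cols: dict[str, list[float]] = {}
    per_node = {
        "DC": degree_centrality(network),
        "BC": betweenness_centrality(network),
        "CC": closeness_centrality(network),
        "SC": subgraph_centrality(network),
        "EC": eigenvector_centrality(network, tol=cfg.ec_tol, max_iter=cfg.ec_max_iter),
        "IC": information_centrality(network),
        "NC": nc_centrality(network),
        "PeC": pec_score(network, expr, floor_negative=cfg.pec_floor_negative),
        "WDC": wdc_score(network, expr, lam=cfg.wdc_lambda,
                         floor_negative=cfg.wdc_floor_negative),
        "ION": ion_score(network, orth, alpha=cfg.ion_alpha,
                         tol=cfg.ion_tol, max_iter=cfg.ion_max_iter),
    }
    for name, mapping in per_node.items():
        cols[name] = [mapping[v] for v in nodes]
    raw = pd.DataFrame(cols, index=pd.Index(nodes, name="protein"))
    normalized = normalize_features(raw)

    loc = localization if localization is not None else pd.DataFrame(columns=list(cfg.compartments))
    for comp in cfg.compartments:
        if comp in loc.columns:
            col = loc[comp].reindex(nodes).fillna(0)
        else:
            col = pd.Series(0, index=nodes)
        normalized[comp] = (col > 0).astype(float).to_numpy()
    return normalized
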