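"""Independent brute-force oracles for the centrality and AUC tests.

Deliberately naive implementations by a different route than the package:
hand-rolled BFS and shortest-path enumeration, dense matrix exponentials
and eigendecompositions, Laplacian pseudoinverse resistances, and the
rank-sum AUC. Used only to cross-check results on small graphs.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from gepess.io import InteractionNetwork


def _adjacency(network: InteractionNetwork):
    nodes = sorted(network.graph.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v in network.graph.edges:
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
    return nodes, a


def _bfs_distances(adj: dict[str, set], source: str) -> dict[str, int]:
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def degree_oracle(network: InteractionNetwork) -> dict[str, float]:
    nodes, a = _adjacency(network)
    sums = a.sum(axis=1)
    return {v: float(s) for v, s in zip(nodes, sums)}


def _all_shortest_paths(adj, dist, source, target):
    # enumerate every shortest source->target path by backtracking
    if target not in dist:
        return
    def extend(path):
        u = path[-1]
        if u == target:
            yield list(path)
            return
        for w in adj[u]:
            if dist.get(w) == dist[u] + 1 and dist[w] <= dist.get(target, -1):
                path.append(w)
                yield from extend(path)
                path.pop()
    yield from extend([source])


def betweenness_oracle(network: InteractionNetwork) -> dict[str, float]:
    g = network.graph
    adj = {v: set(g[v]) for v in g.nodes}
    nodes = sorted(g.nodes)
    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        dist = _bfs_distances(adj, s)
        for t in nodes[i + 1:]:
            if t == s or t not in dist:
                continue
            paths = list(_all_shortest_paths(adj, dist, s, t))
            if not paths:
                continue
            through = {}
            for p in paths:
                for v in p[1:-1]:
                    through[v] = through.get(v, 0) + 1
            for v, c in through.items():
                bc[v] += c / len(paths)
    return bc


def closeness_oracle(network: InteractionNetwork) -> dict[str, float]:
    g = network.graph
    adj = {v: set(g[v]) for v in g.nodes}
    out = {}
    for v in g.nodes:
        dist = _bfs_distances(adj, v)
        total = sum(dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def subgraph_oracle(network: InteractionNetwork) -> dict[str, float]:
    nodes, a = _adjacency(network)
    diag = scipy.linalg.expm(a).diagonal()
    return {v: float(d) for v, d in zip(nodes, diag)}


def eigenvector_oracle(network: InteractionNetwork) -> dict[str, float]:
    import networkx as nx
    g = network.graph
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    comp = sorted(comps[0])
    out = {v: 0.0 for v in g.nodes}
    if len(comp) == 1:
        out[comp[0]] = 1.0
        return out
    sub = InteractionNetwork(g.subgraph(comp).copy())
    nodes, a = _adjacency(sub)
    w, v = np.linalg.eigh(a)
    vec = np.abs(v[:, np.argmax(w)])
    vec /= np.linalg.norm(vec)
    for node, val in zip(nodes, vec):
        out[node] = float(val)
    return out


def information_oracle(network: InteractionNetwork) -> dict[str, float]:
    """Via effective resistances from the Laplacian pseudoinverse."""
    import networkx as nx
    g = network.graph
    out = {}
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        n = len(comp)
        if n == 1:
            out[comp[0]] = 0.0
            continue
        sub = InteractionNetwork(g.subgraph(comp).copy())
        nodes, a = _adjacency(sub)
        lap = np.diag(a.sum(axis=1)) - a
        lp = np.linalg.pinv(lap)
        d = np.diag(lp)
        r = d[:, None] + d[None, :] - 2 * lp
        np.fill_diagonal(r, 0.0)
        for v, total in zip(nodes, r.sum(axis=1)):
            out[v] = float(n / total)
    return out


def ecc_oracle(network: InteractionNetwork, u: str, v: str) -> float:
    g = network.graph
    z = sum(1 for w in g.nodes if w not in (u, v)
            and g.has_edge(u, w) and g.has_edge(v, w))
    denom = min(g.degree(u) - 1, g.degree(v) - 1)
    return z / denom if denom > 0 else 0.0


def nc_oracle(network: InteractionNetwork) -> dict[str, float]:
    g = network.graph
    return {v: sum(ecc_oracle(network, v, u) for u in g[v]) for v in g.nodes}


def auc_rank_sum_oracle(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(equal)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
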