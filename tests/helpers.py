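"""Shared test utilities: graph builders and independent oracles.

The oracles here deliberately use different algorithms from the package
(union-find instead of DFS, exhaustive subset scans instead of recursive
expansion, BFS over a pairwise clique-adjacency matrix instead of
subset-keyed union-find) so agreement is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np

from penkit import ResidueID, ThresholdedPEN


def graph_from_edges(n: int, edges, cutoff=-1.0, channel="total") -> ThresholdedPEN:
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    residues = [ResidueID("A", i + 1, None, "ALA") for i in range(n)]
    return ThresholdedPEN(residues=residues, cutoff_e=cutoff,
                          channel=channel, adjacency=adj)


def random_graph(n: int, p: float, seed: int) -> ThresholdedPEN:
    rng = np.random.default_rng(seed)
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    return graph_from_edges(n, zip(*np.nonzero(adj)))


# ---------------------------------------------------------------------------
# oracles

def union_find_components(g: ThresholdedPEN) -> set[frozenset[int]]:
    """Connected components by union-find (path-halving + union by index)."""
    parent = list(range(g.n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in g.edges():
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, set[int]] = {}
    for v in range(g.n_nodes):
        groups.setdefault(find(v), set()).add(v)
    return {frozenset(s) for s in groups.values()}


def brute_force_k_cliques(g: ThresholdedPEN, k: int) -> set[frozenset[int]]:
    """All k-subsets whose induced subgraph is complete, by exhaustive scan."""
    out = set()
    for combo in itertools.combinations(range(g.n_nodes), k):
        if all(g.has_edge(a, b) for a, b in itertools.combinations(combo, 2)):
            out.add(frozenset(combo))
    return out


def brute_force_communities(g: ThresholdedPEN, k: int) -> set[frozenset[int]]:
    """Clique-percolation community node sets via pairwise adjacency + BFS."""
    cliques = sorted(brute_force_k_cliques(g, k), key=sorted)
    m = len(cliques)
    adjacent = [[len(cliques[a] & cliques[b]) >= k - 1 for b in range(m)]
                for a in range(m)]
    seen = [False] * m
    out = set()
    for start in range(m):
        if seen[start]:
            continue
        queue, members = [start], []
        seen[start] = True
        while queue:
            c = queue.pop(0)
            members.append(c)
            for d in range(m):
                if adjacent[c][d] and not seen[d]:
                    seen[d] = True
                    queue.append(d)
        out.add(frozenset().union(*(cliques[c] for c in members)))
    return out
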