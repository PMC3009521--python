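"""Network statistics of PEN_e graphs.

Implements the statistics used to compare homologous proteins across an
energy-cutoff sweep:

* clusters — connected components (depth-first search), counted in
  population profiles only at size >= 3;
* LCC — the largest connected component's node count;
* hubs — nodes of degree >= 4, the packing-based convention for protein
  structure networks;
* k-cliques — all complete node subsets of size k (not only maximal
  cliques), enumerated deterministically;
* communities — clique percolation: two k-cliques are adjacent iff they
  share k-1 nodes, and a community is a maximal chain of adjacent
  k-cliques; its size is the number of distinct nodes it covers.

All functions are deterministic: components are ordered by smallest
member, cliques lexicographically, communities by (size descending,
smallest member).
"""

from __future__ import annotations

from dataclasses import dataclass

from .pen_core import ThresholdedPEN


@dataclass(frozen=True)
class Cluster:
    """A connected component of PEN_e."""

    nodes: frozenset[int]

    @property
    def size(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class Clique:
    """A complete subgraph on k nodes (k*(k-1)/2 internal edges)."""

    nodes: tuple[int, ...]

    @property
    def k(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class Community:
    """A maximal set of pairwise percolation-connected k-cliques."""

    cliques: frozenset[Clique]
    node_union: frozenset[int]

    @property
    def size(self) -> int:
        """Number of distinct nodes covered by the member cliques."""
        return len(self.node_union)


def connected_components(g: ThresholdedPEN) -> list[Cluster]:
    """Partition of all nodes into maximal connected sets via iterative DFS."""
    n = g.n_nodes
    seen = [False] * n
    out: list[Cluster] = []
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in g.neighbors(v):
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        out.append(Cluster(frozenset(comp)))
    return out  # starts scan at node 0: already ordered by smallest member


def lcc_size(g: ThresholdedPEN) -> int:
    """Node count of the largest connected component (>= 1 for any graph)."""
    comps = connected_components(g)
    return max((c.size for c in comps), default=0)


def count_clusters(g: ThresholdedPEN, min_size: int = 3) -> int:
    """Number of connected components with at least ``min_size`` nodes."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    return sum(1 for c in connected_components(g) if c.size >= min_size)


def hubs(g: ThresholdedPEN, degree_threshold: int = 4) -> set[int]:
    """Nodes with degree >= ``degree_threshold``."""
    if degree_threshold < 1:
        raise ValueError("degree_threshold must be >= 1")
    deg = g.degree()
    return {i for i in range(g.n_nodes) if deg[i] >= degree_threshold}


def enumerate_k_cliques(g: ThresholdedPEN, k: int) -> list[Clique]:
    """Every size-k complete subgraph, each once, in sorted node order.

    Recursive expansion over increasing node indices: a partial clique is
    only extended with neighbours common to all members and larger than
    the last member, so each k-subset is produced exactly once.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    adj = g.adjacency
    neighbor_sets = [set(g.neighbors(v)) for v in range(g.n_nodes)]
    out: list[Clique] = []

    def extend(clique: list[int], candidates: set[int]) -> None:
        if len(clique) == k:
            out.append(Clique(tuple(clique)))
            return
        for v in sorted(candidates):
            extend(clique + [v], {u for u in candidates & neighbor_sets[v] if u > v})

    for v in range(g.n_nodes):
        extend([v], {u for u in neighbor_sets[v] if u > v})
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def clique_communities(g: ThresholdedPEN, k: int = 3) -> list[Community]:
    """Clique-percolation communities of the k-cliques of PEN_e.

    Two distinct k-cliques are adjacent iff they share k-1 nodes, i.e.
    iff they share a (k-1)-subset; chaining adjacency through shared
    (k-1)-subsets with union-find gives the maximal communities without
    the quadratic pairwise clique comparison.  Every k-clique belongs to
    exactly one community.  Ordered by (size desc, smallest member).
    """
    if k < 3:
        raise ValueError("k must be >= 3 for clique percolation")
    cliques = enumerate_k_cliques(g, k)
    uf = _UnionFind(len(cliques))
    owner: dict[tuple[int, ...], int] = {}
    for idx, c in enumerate(cliques):
        for drop in range(k):
            sub = c.nodes[:drop] + c.nodes[drop + 1:]
            if sub in owner:
                uf.union(owner[sub], idx)
            else:
                owner[sub] = idx
    groups: dict[int, list[Clique]] = {}
    for idx, c in enumerate(cliques):
        groups.setdefault(uf.find(idx), []).append(c)
    comms = [
        Community(cliques=frozenset(cs),
                  node_union=frozenset().union(*(c.nodes for c in cs)))
        for cs in groups.values()
    ]
    comms.sort(key=lambda c: (-c.size, min(c.node_union)))
    return comms


def largest_community_size(g: ThresholdedPEN, k: int = 3) -> int:
    """Max community node-union size; 0 when the graph has no k-clique."""
    comms = clique_communities(g, k)
    return max((c.size for c in comms), default=0)
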