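"""Dense sub-module mining by edge-clustering-value agglomeration.

Edges are ranked by their edge clustering value

    ECV(u, v) = w(u, v) * |N(u) & N(v)|^2 / (|N(u)| * |N(v)|)

with w the edge weight (|r| of the defining condition; 1 when absent) and
N(.) the open neighborhoods. Clusters grow by merging the endpoint
clusters of edges in rank order; a merge is accepted when the merged
cluster is a lambda-module (total within-cluster degree strictly greater
than lambda times its boundary degree) or when the merge strictly raises
the in/out degree ratio above both components'. Two clusters that are each
already lambda-modules are never merged, which keeps bridge edges between
dense blocks from collapsing them.

The lncRNA-PCG dysregulation network is bipartite, so |N(u) & N(v)| = 0
for every edge and ECV is identically zero; the ordering then falls back
to edge weight (descending), then cycle support (the number of triangles
and quadrilaterals through the edge, so that bridge edges in no short
cycle sort last), then lexicographic endpoint ids. This fallback is
deliberate and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

SIZE_MIN = 3
LAMBDA_DEFAULT = 1.0


@dataclass
class SubModule:
    """A node-disjoint dense cluster of the dysregulation network."""

    module_id: int
    nodes: set = field(default_factory=set)
    edges: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.nodes)


def edge_clustering_value(graph: nx.Graph, u, v) -> float:
    """ECV of an existing edge (u, v)."""
    if not graph.has_edge(u, v):
        raise ValueError(f"edge ({u!r}, {v!r}) not in graph")
    nu = set(graph[u])
    nv = set(graph[v])
    common = len(nu & nv)
    if common == 0:
        return 0.0
    w = graph[u][v].get("weight", 1.0)
    return w * common * common / (len(nu) * len(nv))


class _Clusters:
    """Union-find over nodes with per-cluster in/out degree bookkeeping."""

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self.parent = {n: n for n in graph.nodes}
        self.members = {n: {n} for n in graph.nodes}
        self.internal = {n: 0 for n in graph.nodes}  # edges inside cluster

    def find(self, n):
        root = n
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[n] != root:
            self.parent[n], n = root, self.parent[n]
        return root

    def in_out(self, root) -> tuple[int, int]:
        """(total internal degree, boundary edge count) of a cluster."""
        in_deg = 2 * self.internal[root]
        total_deg = sum(self.graph.degree(n) for n in self.members[root])
        return in_deg, total_deg - in_deg

    def merged_in_out(self, ra, rb) -> tuple[int, int]:
        cross = sum(
            1
            for a in self.members[ra]
            for b in self.graph[a]
            if self.find(b) == rb
        )
        internal = self.internal[ra] + self.internal[rb] + cross
        in_deg = 2 * internal
        total = sum(
            self.graph.degree(n)
            for r in (ra, rb)
            for n in self.members[r]
        )
        return in_deg, total - in_deg

    def union(self, ra, rb):
        if len(self.members[ra]) < len(self.members[rb]):
            ra, rb = rb, ra
        cross = sum(
            1
            for a in self.members[rb]
            for b in self.graph[a]
            if self.find(b) == ra
        )
        self.parent[rb] = ra
        self.members[ra] |= self.members.pop(rb)
        self.internal[ra] += self.internal.pop(rb) + cross
        return ra


def _is_lambda_module(in_deg: int, out_deg: int, lam: float) -> bool:
    return in_deg > lam * out_deg


def _cycle_support(graph: nx.Graph, u, v) -> int:
    """Triangles plus quadrilaterals through edge (u, v).

    Bridge edges between otherwise-disjoint dense regions score 0, which
    pushes them to the end of the processing order under weight ties.
    """
    nu = set(graph[u]) - {v}
    nv = set(graph[v]) - {u}
    triangles = len(nu & nv)
    quads = sum(len(set(graph[x]) & nv) for x in nu)
    return triangles + quads


def mine_modules(
    graph: nx.Graph,
    lambda_param: float = LAMBDA_DEFAULT,
    size_min: int = SIZE_MIN,
) -> list[SubModule]:
    """Extract node-disjoint dense sub-modules.

    Deterministic: edge order is (ECV desc, weight desc, lexicographic
    endpoint ids); ties never depend on insertion order.
    """
    if graph.number_of_edges() == 0:
        return []
    if nx.bipartite.is_bipartite(graph):
        logger.info(
            "bipartite network: all ECVs are 0; edge ordering falls back to "
            "edge weight then lexicographic endpoint ids"
        )

    def key(edge):
        u, v = sorted(map(str, edge[:2]))
        ecv = edge_clustering_value(graph, edge[0], edge[1])
        w = graph[edge[0]][edge[1]].get("weight", 1.0)
        support = _cycle_support(graph, edge[0], edge[1])
        return (-ecv, -w, -support, u, v)

    edges = sorted(graph.edges(), key=key)
    cl = _Clusters(graph)

    for u, v in edges:
        ru, rv = cl.find(u), cl.find(v)
        if ru == rv:
            continue  # edge already internal (counted at union time)
        in_u, out_u = cl.in_out(ru)
        in_v, out_v = cl.in_out(rv)
        if _is_lambda_module(in_u, out_u, lambda_param) and _is_lambda_module(
            in_v, out_v, lambda_param
        ):
            continue  # two finished modules: a bridge, keep them apart
        in_m, out_m = cl.merged_in_out(ru, rv)
        ratio_m = in_m / out_m if out_m else float("inf")
        ratio_u = in_u / out_u if out_u else (float("inf") if in_u else 0.0)
        ratio_v = in_v / out_v if out_v else (float("inf") if in_v else 0.0)
        if _is_lambda_module(in_m, out_m, lambda_param) or ratio_m > max(
            ratio_u, ratio_v
        ):
            cl.union(ru, rv)

    roots = sorted(
        {cl.find(n) for n in graph.nodes},
        key=lambda r: (-len(cl.members[r]), str(min(cl.members[r], key=str))),
    )
    modules = []
    for root in roots:
        nodes = cl.members[root]
        if len(nodes) < size_min:
            continue
        sub = graph.subgraph(nodes)
        modules.append(
            SubModule(
                module_id=len(modules) + 1,
                nodes=set(nodes),
                edges=sorted(tuple(sorted(map(str, e))) for e in sub.edges()),
            )
        )
    return modules


def module_membership(
    modules: list[SubModule], roles: dict | None = None
) -> "list[tuple[int, str, str]]":
    """Flat (module_id, gene_id, role) rows for TSV export."""
    rows = []
    for m in modules:
        for n in sorted(m.nodes, key=str):
            role = (roles or {}).get(n, "")
            rows.append((m.module_id, n, role))
    return rows
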