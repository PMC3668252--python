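"""Median-joining haplotype networks.

The classic construction for intraspecific genealogies: start from the
minimum-spanning network (all links that tie the partition-merging minimum,
optionally relaxed by ``epsilon``), repeatedly add quasi-median vectors of
connected triplets when they reduce the network cost, and finally delete
median vectors that end up peripheral. All characters carry weight 1 — a
multi-base indel event is a single mutational step, exactly as it is a
single recoded character.

``cost`` of a network is the weight of a minimum spanning tree over its node
set (the quantity the median-insertion step minimizes). The drawn network
additionally keeps all minimum-tied alternative links, whose summed weight
can exceed the tree weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, islice, product
from pathlib import Path

import networkx as nx

from .errors import DataError, SchemaError, UsageError
from .popseq import HaplotypePanel
from .seqio import Taxon

__all__ = [
    "mutation_distance",
    "MJNetwork",
    "median_joining",
    "export_network",
    "read_edge_tsv",
]

StateVec = tuple[str, ...]


def mutation_distance(x: StateVec, y: StateVec) -> int:
    """Mutational steps between two state vectors.

    Characters with differing non-missing states each count one step; an
    indel character counts 1 regardless of the event's length in bp; N never
    contributes.
    """
    if len(x) != len(y):
        raise SchemaError(
            f"state vectors of length {len(x)} and {len(y)} are not over the "
            "same character schema"
        )
    return sum(1 for a, b in zip(x, y) if a != "N" and b != "N" and a != b)


@dataclass
class MJNetwork:
    graph: nx.Graph
    observed: tuple[str, ...]

    @property
    def cost(self) -> int:
        """Minimum-spanning-tree weight over the final node set."""
        vecs = [self.graph.nodes[n]["states"] for n in sorted(self.graph)]
        return _mst_cost(vecs)

    @property
    def total_edge_weight(self) -> int:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    def median_nodes(self) -> list[str]:
        return [
            n for n, d in self.graph.nodes(data=True) if d["is_median"]
        ]


def _dist_matrix(vecs: list[StateVec]) -> list[list[int]]:
    n = len(vecs)
    d = [[0] * n for _ in range(n)]
    for i in range(n):
        vi = vecs[i]
        for j in range(i + 1, n):
            d[i][j] = d[j][i] = mutation_distance(vi, vecs[j])
    return d


def _prim(d: list[list[int]]) -> list[tuple[int, int]]:
    """Prim's MST on a dense small matrix; returns tree edges.

    Deterministic: ties go to the lowest-index vertex pair.
    """
    n = len(d)
    if n < 2:
        return []
    in_tree = [False] * n
    best = [float("inf")] * n
    parent = [-1] * n
    best[0] = 0
    edges: list[tuple[int, int]] = []
    for _ in range(n):
        u = min(
            (i for i in range(n) if not in_tree[i]), key=lambda i: (best[i], i)
        )
        in_tree[u] = True
        if parent[u] >= 0:
            edges.append((min(parent[u], u), max(parent[u], u)))
        for v in range(n):
            if not in_tree[v] and d[u][v] < best[v]:
                best[v] = d[u][v]
                parent[v] = u
    return edges


def _mst_cost_matrix(d: list[list[int]]) -> int:
    return sum(d[i][j] for i, j in _prim(d))


def _mst_cost(vecs: list[StateVec]) -> int:
    if len(vecs) < 2:
        return 0
    return _mst_cost_matrix(_dist_matrix(vecs))


def _msn_edges(vecs: list[StateVec], epsilon: int) -> list[tuple[int, int, int]]:
    """Minimum-spanning-network links.

    A pair (u, v) is linked iff d(u, v) ≤ minimax(u, v) + epsilon, where the
    minimax distance (the weight at which u and v first join in a Kruskal
    sweep) is the maximum edge on the MST path between them. epsilon = 0
    keeps exactly the MST plus all weight-tied alternatives.
    """
    n = len(vecs)
    if n == 1:
        return []
    d = _dist_matrix(vecs)
    tree_adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j in _prim(d):
        tree_adj[i].append(j)
        tree_adj[j].append(i)
    # minimax via per-source DFS over the tree (n is small)
    minimax = [[0] * n for _ in range(n)]
    for src in range(n):
        stack = [(src, 0)]
        seen = {src}
        while stack:
            u, cur = stack.pop()
            for v in tree_adj[u]:
                if v not in seen:
                    seen.add(v)
                    m = max(cur, d[u][v])
                    minimax[src][v] = m
                    stack.append((v, m))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if d[i][j] <= minimax[i][j] + epsilon:
                edges.append((i, j, d[i][j]))
    return edges


def _quasi_medians(
    a: StateVec, b: StateVec, c: StateVec, cap: int = 81
) -> list[StateVec]:
    """Per character: the majority state, or all three on a three-way split."""
    options = []
    for x, y, z in zip(a, b, c):
        states = (x, y, z)
        maj = [s for s in set(states) if states.count(s) >= 2]
        options.append(sorted(maj) if maj else sorted(set(states)))
    return [tuple(v) for v in islice(product(*options), cap)]


def median_joining(
    panel: HaplotypePanel, epsilon: int = 0, max_medians: int = 64
) -> MJNetwork:
    """Build the median-joining network of a haplotype panel.

    Deterministic given the panel: haplotypes are processed in name order and
    candidate medians in lexicographic state order. Haplotype counts only
    annotate node size; they never influence the topology.
    """
    if not panel.haplotypes:
        raise DataError(f"{panel.locus_name}: empty panel")
    observed = sorted(panel.haplotypes, key=lambda h: h.name)
    names = [h.name for h in observed]
    vecs: list[StateVec] = [h.states for h in observed]
    is_median: list[bool] = [False] * len(vecs)
    n_added = 0

    while n_added < max_medians:
        cost0 = _mst_cost(vecs)
        edges = _msn_edges(vecs, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(vecs))}
        for i, j, _ in edges:
            adj[i].add(j)
            adj[j].add(i)
        existing = set(vecs)
        candidates: set[StateVec] = set()
        for i, j, k in combinations(range(len(vecs)), 3):
            linked = sum(
                1 for (u, v) in ((i, j), (i, k), (j, k)) if v in adj[u]
            )
            if linked < 2:
                continue
            for m in _quasi_medians(vecs[i], vecs[j], vecs[k]):
                if m not in existing:
                    candidates.add(m)
        best: StateVec | None = None
        best_cost = cost0
        for m in sorted(candidates):
            c = _mst_cost(vecs + [m])
            if c < best_cost:
                best, best_cost = m, c
        if best is None:
            break
        n_added += 1
        vecs.append(best)
        names.append(f"mv{n_added}")
        is_median.append(True)

    # obsolete-median cleanup: peripheral (degree ≤ 1) medians are removed
    # and the network rebuilt until stable
    while True:
        edges = _msn_edges(vecs, epsilon)
        degree = [0] * len(vecs)
        for i, j, _ in edges:
            degree[i] += 1
            degree[j] += 1
        drop = [
            i for i in range(len(vecs)) if is_median[i] and degree[i] <= 1
        ]
        if not drop:
            break
        keep = [i for i in range(len(vecs)) if i not in set(drop)]
        vecs = [vecs[i] for i in keep]
        names = [names[i] for i in keep]
        is_median = [is_median[i] for i in keep]

    graph = nx.Graph()
    count = {h.name: panel.total_count(h.name) for h in observed}
    species = {h.name: h.species.value for h in observed}
    for name, vec, med in zip(names, vecs, is_median):
        graph.add_node(
            name,
            states=vec,
            is_median=med,
            count=0 if med else count.get(name, 0),
            species="" if med else species.get(name, ""),
        )
    for i, j, w in _msn_edges(vecs, epsilon):
        graph.add_edge(names[i], names[j], weight=w)
    return MJNetwork(graph=graph, observed=tuple(h.name for h in observed))


def export_network(net: MJNetwork, fmt: str, path: str | Path) -> Path:
    """Write a network as ``edge_tsv`` (plus a ``.nodes.tsv`` companion),
    ``graph_exchange`` (GraphML) or ``dot``; ordering is stable."""
    path = Path(path)
    g = net.graph
    nodes = sorted(g.nodes)
    edges = sorted((min(u, v), max(u, v)) for u, v in g.edges)
    if fmt == "edge_tsv":
        with open(path, "w", newline="\n") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v in edges:
                fh.write(f"{u}\t{v}\t{g[u][v]['weight']}\n")
        nodes_path = path.with_suffix(".nodes.tsv")
        with open(nodes_path, "w", newline="\n") as fh:
            fh.write("name\tspecies\tcount\tis_median\tstates\n")
            for n in nodes:
                d = g.nodes[n]
                fh.write(
                    f"{n}\t{d['species']}\t{d['count']}\t"
                    f"{int(d['is_median'])}\t{''.join(d['states'])}\n"
                )
    elif fmt == "graph_exchange":
        h = nx.Graph()
        for n in nodes:
            d = g.nodes[n]
            h.add_node(
                n,
                states="".join(d["states"]),
                is_median=int(d["is_median"]),
                count=int(d["count"]),
                species=d["species"],
            )
        for u, v in edges:
            h.add_edge(u, v, weight=int(g[u][v]["weight"]))
        nx.write_graphml(h, path)
    elif fmt == "dot":
        with open(path, "w", newline="\n") as fh:
            fh.write("graph haplotypes {\n")
            for n in nodes:
                d = g.nodes[n]
                shape = "point" if d["is_median"] else "circle"
                fh.write(
                    f'  "{n}" [shape={shape}, species="{d["species"]}", '
                    f'count={d["count"]}, is_median={int(d["is_median"])}];\n'
                )
            for u, v in edges:
                fh.write(f'  "{u}" -- "{v}" [label={g[u][v]["weight"]}];\n')
            fh.write("}\n")
    else:
        raise UsageError(f"unknown network format {fmt!r}")
    return path


def read_edge_tsv(path: str | Path) -> nx.Graph:
    """Parse the edge_tsv + nodes.tsv pair back into a graph."""
    path = Path(path)
    g = nx.Graph()
    nodes_path = path.with_suffix(".nodes.tsv")
    with open(nodes_path) as fh:
        next(fh)
        for line in fh:
            name, species, count, is_median, states = line.rstrip("\n").split("\t")
            g.add_node(
                name,
                species=species,
                count=int(count),
                is_median=bool(int(is_median)),
                states=tuple(states),
            )
    with open(path) as fh:
        next(fh)
        for line in fh:
            u, v, w = line.rstrip("\n").split("\t")
            g.add_edge(u, v, weight=int(w))
    return g
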