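"""Variable-relationship graphs from the association matrix.

Associations are turned into distances (d = 1 - a), the minimum
spanning tree of the complete distance graph keeps, for each variable,
its most economical connections to the rest, and an optional
augmentation step adds back strong non-tree edges when they improve a
pluggable graph-regularity functional (the "maximally regular graph").
The default functional accepts nothing, so the default MRG equals the
MST — the published variable graphs are tree-shaped.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from typing import Callable

import networkx as nx
import numpy as np

from .autocm import AssociationMatrix
from .cohort import INDICATOR_NAMES


@dataclass
class VariableGraph:
    graph: nx.Graph  # edges carry a 'strength' attribute in [0, 1]
    kind: str  # "MST" or "MRG"

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return sorted(
            (min(u, v), max(u, v), float(d["strength"]))
            for u, v, d in self.graph.edges(data=True)
        )

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)


def association_to_distance(a: AssociationMatrix) -> np.ndarray:
    """d_ij = 1 - a_ij: symmetric, zero diagonal, order-reversing in a."""
    d = 1.0 - np.asarray(a.values, dtype=float)
    np.fill_diagonal(d, 0.0)
    return d


def minimum_spanning_tree(d: np.ndarray, names: list[str]) -> VariableGraph:
    """Kruskal MST with deterministic tie-breaking.

    Edges are processed by (weight, lexicographic node pair), so equal
    weight edges always resolve the same way and the output is
    byte-stable across runs.  Edge strengths are annotated as 1 - d.
    """
    d = np.asarray(d, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.isfinite(d).all():
        raise ValueError("distance matrix must be finite")
    N = len(names)
    if N != d.shape[0]:
        raise ValueError("names do not match distance matrix size")
    edges = []
    for i in range(N):
        for j in range(i + 1, N):
            u, v = sorted([names[i], names[j]])
            edges.append((float(d[i, j]), u, v))
    edges.sort()
    uf = nx.utils.UnionFind(names)
    g = nx.Graph()
    g.add_nodes_from(names)
    for w, u, v in edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            g.add_edge(u, v, strength=1.0 - w)
        if g.number_of_edges() == N - 1:
            break
    return VariableGraph(g, "MST")


RegularityFunctional = Callable[[nx.Graph], float]


def degree_two_count(g: nx.Graph) -> float:
    """Example regularity functional: number of degree-2 nodes."""
    return float(sum(1 for _, deg in g.degree() if deg == 2))


def mrg_augment(
    tree: VariableGraph,
    a: AssociationMatrix,
    regularity: RegularityFunctional | None = None,
    budget: int | None = None,
) -> VariableGraph:
    """Greedy augmentation of the MST toward a maximally regular graph.

    Non-tree edges are visited in decreasing association strength (ties
    lexicographic); an edge is added iff the regularity functional
    strictly increases.  ``regularity=None`` (the default) accepts no
    edge, so the result is the MST relabeled as the MRG.  ``budget``
    caps the number of added edges.
    """
    if budget is not None and budget < 0:
        raise ValueError("budget must be non-negative")
    if set(tree.nodes) != set(a.variable_names):
        raise ValueError("tree nodes do not match association matrix")
    g = tree.graph.copy()
    added = 0
    if regularity is not None:
        candidates = [
            (u, v, s) for u, v, s in a.top_edges() if not g.has_edge(u, v)
        ]
        for u, v, s in candidates:
            if budget is not None and added >= budget:
                break
            current = regularity(g)
            g.add_edge(u, v, strength=s)
            if regularity(g) > current:
                added += 1
            else:
                g.remove_edge(u, v)
    return VariableGraph(g, "MRG")


# ---------------------------------------------------------------------------
# Serialization

FORMATS = ("graphml", "dot", "csv")


def _prepare(g: VariableGraph) -> nx.Graph:
    out = g.graph.copy()
    for node in out.nodes:
        out.nodes[node]["category"] = (
            "group" if node in INDICATOR_NAMES else "variable"
        )
    for u, v, d in out.edges(data=True):
        d["label"] = f"{d['strength']:.2f}"
    return out


def export_graph(g: VariableGraph, path, format: str = "graphml") -> None:
    """Write the graph with full-precision ``strength`` attributes and
    2-decimal ``label`` renderings; group-indicator nodes carry
    ``category="group"``."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {FORMATS}")
    gg = _prepare(g)
    gg.graph["kind"] = g.kind
    if format == "graphml":
        nx.write_graphml(gg, path)
    elif format == "dot":
        with open(path, "w") as f:
            f.write(f'graph "{g.kind}" {{\n')
            for node, d in sorted(gg.nodes(data=True)):
                f.write(f'  "{node}" [category="{d["category"]}"];\n')
            for u, v, s in g.edges:
                f.write(
                    f'  "{u}" -- "{v}" [strength="{s!r}", label="{s:.2f}"];\n'
                )
            f.write("}\n")
    else:
        with open(path, "w", newline="") as f:
            writer = csv.writer(f)
            writer.writerow(["u", "v", "strength"])
            for u, v, s in g.edges:
                writer.writerow([u, v, repr(s)])


_DOT_EDGE = re.compile(r'"(.*?)" -- "(.*?)" \[strength="(.*?)"')
_DOT_NODE = re.compile(r'"(.*?)" \[category=')


def import_graph(path, format: str = "graphml") -> VariableGraph:
    """Re-read a graph written by :func:`export_graph` (lossless for the
    node set, edge set and strengths)."""
    if format == "graphml":
        gg = nx.read_graphml(path)
        kind = gg.graph.get("kind", "MST")
        g = nx.Graph()
        g.add_nodes_from(gg.nodes)
        for u, v, d in gg.edges(data=True):
            g.add_edge(u, v, strength=float(d["strength"]))
        return VariableGraph(g, kind)
    if format == "dot":
        g = nx.Graph()
        kind = "MST"
        with open(path) as f:
            for line in f:
                if line.startswith("graph"):
                    m = re.match(r'graph "(.*?)"', line)
                    if m:
                        kind = m.group(1)
                m = _DOT_EDGE.search(line)
                if m:
                    g.add_edge(m.group(1), m.group(2), strength=float(m.group(3)))
                    continue
                m = _DOT_NODE.search(line)
                if m:
                    g.add_node(m.group(1))
        return VariableGraph(g, kind)
    if format == "csv":
        g = nx.Graph()
        with open(path, newline="") as f:
            for row in csv.DictReader(f):
                g.add_edge(row["u"], row["v"], strength=float(row["strength"]))
        return VariableGraph(g, "MST")
    raise ValueError(f"unknown format {format!r}")
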