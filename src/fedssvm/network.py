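"""Agent communication graphs and Metropolis mixing weights.

Agents use 1-based indices at the interface. Weights follow the Metropolis
rule: omega_ij = 1/(max(deg i, deg j) + 1) on edges, zero on non-edges, and
a compensating diagonal, which yields a symmetric doubly stochastic matrix
whose second-largest eigenvalue modulus is < 1 on any connected graph.
Self-loops live only on the diagonal of omega, never in the edge set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np

__all__ = ["CommGraph", "build_topology", "metropolis_weights",
           "save_graph", "load_graph"]

_TOPOLOGIES = ("complete", "ring", "path", "star", "erdos_renyi")


@dataclass
class CommGraph:
    m: int
    edges: frozenset  # frozenset of frozenset({i, j}) pairs, 1-based
    topology_kind: str
    weights: Optional[np.ndarray] = None

    def degree(self, i: int) -> int:
        return sum(1 for e in self.edges if i in e)

    def neighbors(self, i: int) -> set[int]:
        return {next(iter(e - {i})) for e in self.edges if i in e}

    def edge_list(self) -> list[tuple[int, int]]:
        return sorted(tuple(sorted(e)) for e in self.edges)


def _as_nx(graph: CommGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(1, graph.m + 1))
    g.add_edges_from(graph.edge_list())
    return g


def build_topology(kind: str, m: int, p: float = 0.5, seed: int = 0) -> CommGraph:
    """Build a connected graph of one of the stock kinds (weights unset).

    erdos_renyi resamples with a fresh sub-seed (up to 1000 attempts) until
    the sample is connected.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if kind == "complete":
        g = nx.complete_graph(m)
    elif kind == "ring":
        g = nx.cycle_graph(m)
    elif kind == "path":
        g = nx.path_graph(m)
    elif kind == "star":
        g = nx.star_graph(m - 1)  # node 0 is the hub
    elif kind == "erdos_renyi":
        if not (0.0 < p <= 1.0):
            raise ValueError("p must lie in (0, 1] for erdos_renyi")
        g = None
        for attempt in range(1000):
            cand = nx.gnp_random_graph(m, p, seed=seed * 1009 + attempt)
            if m == 1 or nx.is_connected(cand):
                g = cand
                break
        if g is None:
            raise RuntimeError(
                f"erdos_renyi(m={m}, p={p}) not connected after 1000 attempts")
    else:
        raise ValueError(f"unknown topology kind {kind!r}; "
                         f"expected one of {_TOPOLOGIES}")
    edges = frozenset(frozenset((u + 1, v + 1)) for u, v in g.edges())
    return CommGraph(m=m, edges=edges, topology_kind=kind)


def metropolis_weights(graph: CommGraph) -> CommGraph:
    """Attach the Metropolis doubly stochastic weight matrix.

    Requires a connected graph; validates double stochasticity on the way out.
    """
    m = graph.m
    if m > 1 and not nx.is_connected(_as_nx(graph)):
        raise ValueError("graph must be connected")
    deg = np.array([graph.degree(i) for i in range(1, m + 1)])
    w = np.zeros((m, m))
    for i, j in graph.edge_list():
        val = 1.0 / (max(deg[i - 1], deg[j - 1]) + 1.0)
        w[i - 1, j - 1] = val
        w[j - 1, i - 1] = val
    np.fill_diagonal(w, 1.0 - w.sum(axis=1))
    assert np.allclose(w.sum(axis=0), 1.0) and np.allclose(w.sum(axis=1), 1.0)
    return CommGraph(m=m, edges=graph.edges, topology_kind=graph.topology_kind,
                     weights=w)


def save_graph(graph: CommGraph, edge_path, meta_path) -> None:
    """Edge list as 'i j' lines plus a JSON sidecar with m and kind."""
    lines = [f"{i} {j}" for i, j in graph.edge_list()]
    Path(edge_path).write_text("\n".join(lines) + ("\n" if lines else ""))
    Path(meta_path).write_text(json.dumps(
        {"m": graph.m, "topology_kind": graph.topology_kind}))


def load_graph(edge_path, meta_path) -> CommGraph:
    meta = json.loads(Path(meta_path).read_text())
    edges = set()
    for line in Path(edge_path).read_text().splitlines():
        if line.strip():
            i, j = map(int, line.split())
            edges.add(frozenset((i, j)))
    return CommGraph(m=meta["m"], edges=frozenset(edges),
                     topology_kind=meta["topology_kind"])
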