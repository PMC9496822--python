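"""Core graph and partition containers.

``BinaryNetwork`` is a minimal immutable view of a simple undirected,
unweighted graph: exactly what edge-count binarization of a connectivity
matrix produces.  ``Partition`` is a disjoint cover of the node set, the
decoded form of a community-label chromosome.  Both convert to/from
:mod:`networkx` for interop, but the detection core works on the plain
arrays stored here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import InvalidInputError


@dataclass(frozen=True)
class BinaryNetwork:
    """Simple undirected unweighted graph with named nodes.

    Parameters
    ----------
    n_nodes:
        Number of nodes; node indices are ``0..n_nodes-1``.
    edges:
        Unordered node pairs, stored canonically as sorted ``(i, j)`` tuples
        with ``i < j``; no self-loops, no duplicates.
    node_names:
        Ordered unique labels, one per node (e.g. electrode names).
    """

    n_nodes: int
    edges: tuple[tuple[int, int], ...]
    node_names: tuple[str, ...]

    def __post_init__(self):
        if self.n_nodes < 1:
            raise InvalidInputError("network must have at least one node")
        if len(self.node_names) != self.n_nodes:
            raise InvalidInputError("node_names length must equal n_nodes")
        if len(set(self.node_names)) != self.n_nodes:
            raise InvalidInputError("node_names must be unique")
        canon = []
        seen = set()
        for u, v in self.edges:
            if u == v:
                raise InvalidInputError(f"self-loop on node {u}")
            if not (0 <= u < self.n_nodes and 0 <= v < self.n_nodes):
                raise InvalidInputError(f"edge ({u},{v}) out of range")
            e = (u, v) if u < v else (v, u)
            if e in seen:
                raise InvalidInputError(f"duplicate edge {e}")
            seen.add(e)
            canon.append(e)
        object.__setattr__(self, "edges", tuple(sorted(canon)))

    @classmethod
    def from_edges(
        cls,
        n_nodes: int,
        edges: Iterable[tuple[int, int]],
        node_names: Sequence[str] | None = None,
    ) -> "BinaryNetwork":
        names = tuple(node_names) if node_names is not None else tuple(
            str(i) for i in range(n_nodes)
        )
        return cls(n_nodes=n_nodes, edges=tuple(edges), node_names=names)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Endpoint index arrays (u, v), each of length n_edges (cached)."""
        cached = self.__dict__.get("_edge_arrays")
        if cached is None:
            if not self.edges:
                cached = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
            else:
                arr = np.asarray(self.edges, dtype=np.int64)
                cached = (arr[:, 0], arr[:, 1])
            object.__setattr__(self, "_edge_arrays", cached)
        return cached

    def degrees(self) -> np.ndarray:
        cached = self.__dict__.get("_degrees")
        if cached is None:
            cached = np.zeros(self.n_nodes, dtype=np.int64)
            u, v = self.edge_arrays()
            np.add.at(cached, u, 1)
            np.add.at(cached, v, 1)
            object.__setattr__(self, "_degrees", cached)
        return cached

    def adjacency_lists(self) -> list[list[int]]:
        cached = self.__dict__.get("_adjacency")
        if cached is None:
            cached = [[] for _ in range(self.n_nodes)]
            for u, v in self.edges:
                cached[u].append(v)
                cached[v].append(u)
            object.__setattr__(self, "_adjacency", cached)
        return cached

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, node_names: Sequence[str] | None = None) -> "BinaryNetwork":
        nodes = sorted(g.nodes())
        index = {n: i for i, n in enumerate(nodes)}
        if node_names is None:
            node_names = [str(n) for n in nodes]
        edges = [(index[u], index[v]) for u, v in g.edges() if u != v]
        return cls.from_edges(len(nodes), edges, node_names)


@dataclass(frozen=True)
class Partition:
    """Disjoint cover of ``0..n_nodes-1`` into nonempty groups.

    Groups are canonically ordered by their smallest member, and stored as
    sorted tuples.
    """

    groups: tuple[tuple[int, ...], ...]
    n_nodes: int

    def __post_init__(self):
        seen: set[int] = set()
        for g in self.groups:
            if not g:
                raise InvalidInputError("empty group in partition")
            for node in g:
                if not (0 <= node < self.n_nodes):
                    raise InvalidInputError(f"node {node} out of range")
                if node in seen:
                    raise InvalidInputError(f"node {node} appears twice")
                seen.add(node)
        if len(seen) != self.n_nodes:
            raise InvalidInputError("partition does not cover all nodes")
        canon = tuple(sorted((tuple(sorted(g)) for g in self.groups), key=lambda g: g[0]))
        object.__setattr__(self, "groups", canon)

    @classmethod
    def from_labels(cls, labels: Sequence[int]) -> "Partition":
        labels = np.asarray(labels)
        groups: dict[int, list[int]] = {}
        for node, lab in enumerate(labels):
            groups.setdefault(int(lab), []).append(node)
        return cls(groups=tuple(tuple(g) for g in groups.values()), n_nodes=len(labels))

    def labels(self) -> np.ndarray:
        """Community id per node, numbered 0..k-1 by smallest group member."""
        out = np.empty(self.n_nodes, dtype=np.int64)
        for cid, group in enumerate(self.groups):
            for node in group:
                out[node] = cid
        return out

    @property
    def n_communities(self) -> int:
        return len(self.groups)

    def group_sets(self) -> list[frozenset[int]]:
        return [frozenset(g) for g in self.groups]
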