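"""Partition-quality metrics: modularity Q and normalized mutual information.

Modularity follows Newman's community edge-fraction formulation
``Q = sum_i (e_ii - a_i^2)`` where ``e`` is the k x k matrix of edge
fractions between communities and ``a_i`` its row sums; NMI is the
entropy-normalized mutual information between two partitions
(``2 I(p1; p2) / (H(p1) + H(p2))``, the Danon form).  A brute-force
exhaustive modularity maximizer is provided as a small-graph oracle for
validating stochastic search results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, InvalidParameterError, UndefinedMetricError
from .network import BinaryNetwork, Partition


@dataclass(frozen=True)
class CommunityEdgeMatrix:
    """Edge-fraction matrix ``e`` (k x k) and its row sums ``a``.

    ``e[i][j]`` holds half the fraction of edges joining communities i and j
    for i != j (so the full between-pair fraction is ``e[i][j] + e[j][i]``),
    and ``e[i][i]`` the fraction of edges internal to community i; all
    entries of ``e`` sum to 1 on any graph with at least one edge.
    """

    e: np.ndarray
    a: np.ndarray


def community_edge_matrix(network: BinaryNetwork, partition: Partition) -> CommunityEdgeMatrix:
    if partition.n_nodes != network.n_nodes:
        raise InvalidInputError("partition does not match network size")
    m = network.n_edges
    if m == 0:
        raise UndefinedMetricError("modularity is undefined on an edgeless network")
    k = partition.n_communities
    labels = partition.labels()
    e = np.zeros((k, k), dtype=float)
    for u, v in network.edges:
        cu, cv = labels[u], labels[v]
        if cu == cv:
            e[cu, cu] += 1.0
        else:
            e[cu, cv] += 0.5
            e[cv, cu] += 0.5
    e /= m
    return CommunityEdgeMatrix(e=e, a=e.sum(axis=1))


def modularity(network: BinaryNetwork, partition: Partition) -> float:
    """Modularity Q of a partition: ``sum_i (e_ii - a_i^2)``.

    Positive Q means more intra-community edges than a degree-preserving
    random graph would give; Q > 0.3 is the conventional threshold for
    "this network has community structure".
    """
    mat = community_edge_matrix(network, partition)
    return float(np.trace(mat.e) - np.sum(mat.a**2))


def modularity_from_labels(
    labels: np.ndarray,
    edge_u: np.ndarray,
    edge_v: np.ndarray,
    degrees: np.ndarray,
    n_edges: int,
) -> float:
    """Fast Q for a label vector, used in the optimizer's inner loop.

    Equivalent to :func:`modularity`; computed as intra-edge fraction minus
    the squared community degree fractions.  ``labels`` must be small
    non-negative integers.
    """
    if n_edges == 0:
        raise UndefinedMetricError("modularity is undefined on an edgeless network")
    intra = int(np.count_nonzero(labels[edge_u] == labels[edge_v]))
    deg_c = np.bincount(labels, weights=degrees)
    two_m = 2.0 * n_edges
    return intra / n_edges - float(np.sum((deg_c / two_m) ** 2))


@dataclass(frozen=True)
class ConfusionTable:
    """Shared-node counts between two partitions' communities."""

    C: np.ndarray
    N: int

    @property
    def row_sums(self) -> np.ndarray:
        return self.C.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.C.sum(axis=0)


def confusion_table(p1: Partition, p2: Partition) -> ConfusionTable:
    if p1.n_nodes != p2.n_nodes:
        raise InvalidInputError("partitions must cover the same node set")
    l1, l2 = p1.labels(), p2.labels()
    C = np.zeros((p1.n_communities, p2.n_communities), dtype=np.int64)
    np.add.at(C, (l1, l2), 1)
    return ConfusionTable(C=C, N=p1.n_nodes)


def nmi(p1: Partition, p2: Partition) -> float:
    """Normalized mutual information between two partitions, in [0, 1].

    1 means identical groupings (up to relabeling), 0 means the partitions
    carry no information about each other.  When both partitions are the
    single whole-node-set community the entropies vanish; the value is then
    defined as 1 (the partitions are necessarily identical).
    """
    tab = confusion_table(p1, p2)
    C, N = tab.C.astype(float), tab.N
    ci = tab.row_sums.astype(float)
    cj = tab.col_sums.astype(float)
    h1 = -float(np.sum(ci / N * np.log(ci / N)))
    h2 = -float(np.sum(cj / N * np.log(cj / N)))
    if h1 + h2 == 0.0:
        # both single-community over the same nodes -> identical
        return 1.0
    nz = C > 0
    mi = float(np.sum(C[nz] / N * np.log(C[nz] * N / np.outer(ci, cj)[nz])))
    val = 2.0 * mi / (h1 + h2)
    return min(1.0, max(0.0, val))


def pairwise_stability(partitions: Sequence[Partition]) -> float:
    """Mean NMI over all unordered pairs: a run-to-run stability score."""
    if len(partitions) < 2:
        raise InvalidInputError("need at least two partitions for stability")
    vals = [nmi(a, b) for a, b in combinations(partitions, 2)]
    return float(np.mean(vals))


def _set_partitions(n: int):
    """Yield all set partitions of range(n) as label tuples (restricted growth)."""
    labels = [0] * n

    def rec(i: int, max_used: int):
        if i == n:
            yield tuple(labels)
            return
        for lab in range(max_used + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_used, lab))

    yield from rec(1, 0) if n > 0 else iter(())


def exhaustive_best_partition(network: BinaryNetwork) -> tuple[Partition, float]:
    """Enumerate every partition of the node set; return the Q-maximizer.

    Ties are broken by the lexicographically smallest canonical label
    string.  Refuses graphs with more than 10 nodes (Bell numbers explode).
    """
    n = network.n_nodes
    if n > 10:
        raise InvalidParameterError("exhaustive search limited to <= 10 nodes")
    if network.n_edges == 0:
        raise UndefinedMetricError("modularity is undefined on an edgeless network")
    u, v = network.edge_arrays()
    deg = network.degrees()
    best_labels: tuple[int, ...] | None = None
    best_q = -math.inf
    for labels in _set_partitions(n):
        arr = np.asarray(labels, dtype=np.int64)
        q = modularity_from_labels(arr, u, v, deg, network.n_edges)
        if q > best_q + 1e-12 or (abs(q - best_q) <= 1e-12 and (best_labels is None or labels < best_labels)):
            best_q = max(q, best_q)
            best_labels = labels
    assert best_labels is not None
    return Partition.from_labels(best_labels), float(best_q)
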