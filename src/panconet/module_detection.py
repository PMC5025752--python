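"""Newman leading-eigenvector modularity partitioning.

The modularity of a partition of a simple undirected graph is
Q = Σ_c (e_c/m − (d_c/2m)²), the fraction of within-module edges minus its
expectation under the degree-preserving null. The leading-eigenvector
method bisects recursively: the dominant eigenvector of the (generalized)
modularity matrix B splits nodes by component sign; a group whose leading
eigenvalue is non-positive, or whose sign split does not increase Q, is
indivisible. Edge signs from the co-expression stage are bookkeeping only —
the graph is partitioned as unweighted and unsigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "ModulePartition",
    "modularity_matrix",
    "modularity_Q",
    "leading_eigenvector_partition",
]


@dataclass
class ModulePartition:
    """Gene → module assignment with the partition's modularity.

    ``labels`` maps node → non-negative module id, or −1 for nodes left in
    modules smaller than ``min_size`` ("exceptional" nodes). In
    :func:`modularity_Q`, every −1 node is scored as its own singleton
    module, so ``q`` stays self-consistent with the relabeled partition.
    """

    labels: dict[str, int]
    q: float
    min_size: int

    @property
    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for m in self.labels.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    def modules(self) -> dict[int, set]:
        out: dict[int, set] = {}
        for node, m in self.labels.items():
            if m >= 0:
                out.setdefault(m, set()).add(node)
        return out


def modularity_matrix(graph: nx.Graph, node_subset=None) -> tuple[np.ndarray, list]:
    """The (generalized) modularity matrix and its node order.

    Full graph: B_ij = A_ij − k_i k_j / (2m). For a node subset g during
    recursive bisection, the generalized form subtracts each row sum on the
    diagonal: B^(g)_ij = B_ij − δ_ij Σ_{k∈g} B_ik, so that in-group moves
    conserve Q.
    """
    m = graph.number_of_edges()
    if m == 0:
        raise ValueError("modularity matrix of an empty graph is undefined")
    nodes = sorted(graph.nodes)
    a = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    k = a.sum(axis=1)
    b = a - np.outer(k, k) / (2.0 * m)
    if node_subset is None:
        return b, nodes
    sub = sorted(node_subset)
    idx = [nodes.index(n) for n in sub]
    bg = b[np.ix_(idx, idx)].copy()
    bg[np.diag_indices_from(bg)] -= bg.sum(axis=1)
    return bg, sub


def modularity_Q(graph: nx.Graph, labels: dict) -> float:
    """Modularity Q = Σ_c (e_c/m − (d_c/2m)²) of a labeling.

    Nodes labeled −1 are each scored as a singleton module.
    """
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    resolved = {}
    singleton = -1
    for node, lab in labels.items():
        if lab == -1:
            resolved[node] = ("singleton", singleton)
            singleton -= 1
        else:
            resolved[node] = ("module", lab)
    within: dict = {}
    degree: dict = {}
    for node in graph.nodes:
        degree[resolved[node]] = degree.get(resolved[node], 0) + graph.degree(node)
    for u, v in graph.edges:
        if resolved[u] == resolved[v]:
            within[resolved[u]] = within.get(resolved[u], 0) + 1
    q = 0.0
    for mod, d in degree.items():
        e = within.get(mod, 0)
        q += e / m - (d / (2.0 * m)) ** 2
    return q


def _leading_eigenpair(b: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = np.linalg.eigh(b)
    return float(vals[-1]), vecs[:, -1]


def _split_once(graph_b: np.ndarray, nodes: list, m: int, eig_tol: float):
    """Attempt one sign-split of a group; returns (group_plus, group_minus)
    or None when the group is indivisible."""
    lam, v = _leading_eigenpair(graph_b)
    if lam <= eig_tol:
        return None
    # fix the ±v ambiguity: component of the lexicographically smallest node >= 0
    if v[0] < 0:
        v = -v
    s = np.where(v >= 0, 1.0, -1.0)
    if np.all(s == s[0]):
        return None
    delta_q = (s @ graph_b @ s) / (4.0 * m)
    if delta_q <= 0:
        return None
    plus = [n for n, si in zip(nodes, s) if si > 0]
    minus = [n for n, si in zip(nodes, s) if si < 0]
    return plus, minus


def leading_eigenvector_partition(
    graph: nx.Graph, min_size: int = 10, eig_tol: float = 1e-10
) -> ModulePartition:
    """Recursive leading-eigenvector bisection of a graph.

    Runs independently on each connected component. Every accepted split
    strictly increases Q; groups whose leading eigenvalue is ≤ ``eig_tol``
    or whose sign split would not raise Q stay whole. Final modules with
    fewer than ``min_size`` nodes are relabeled −1. The eigenvector sign is
    fixed by requiring the component of the lexicographically smallest node
    in the group to be ≥ 0, making the partition deterministic.
    """
    if graph.number_of_edges() == 0:
        labels = {n: -1 for n in graph.nodes}
        return ModulePartition(labels, modularity_Q(graph, labels), min_size)
    m = graph.number_of_edges()
    nodes_all = sorted(graph.nodes)
    a = nx.to_numpy_array(graph, nodelist=nodes_all, weight=None)
    k = a.sum(axis=1)
    b_full = a - np.outer(k, k) / (2.0 * m)
    pos = {n: i for i, n in enumerate(nodes_all)}

    final_groups: list[list] = []

    def recurse(nodes: list) -> None:
        idx = [pos[n] for n in nodes]
        bg = b_full[np.ix_(idx, idx)].copy()
        if len(nodes) < len(nodes_all):
            bg[np.diag_indices_from(bg)] -= bg.sum(axis=1)
        if len(nodes) == 1:
            final_groups.append(nodes)
            return
        result = _split_once(bg, nodes, m, eig_tol)
        if result is None:
            final_groups.append(nodes)
            return
        plus, minus = result
        recurse(sorted(plus))
        recurse(sorted(minus))

    for comp in nx.connected_components(graph):
        recurse(sorted(comp))

    labels: dict = {}
    next_id = 0
    for group in sorted(final_groups, key=lambda g: (-len(g), g[0])):
        if len(group) >= min_size:
            for n in group:
                labels[n] = next_id
            next_id += 1
        else:
            for n in group:
                labels[n] = -1
    q = modularity_Q(graph, labels)
    return ModulePartition(labels, q, min_size)
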