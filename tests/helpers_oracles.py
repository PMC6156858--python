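"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: the hypergeometric tail
is an exact rational enumeration, the spin-glass optimum an exhaustive search
over all set partitions, the authority vector a dense eigendecomposition, and
the ancestor set a depth-first walk.
"""

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n), by rational enumeration."""
    total = comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, x) * comb(N - K, n - x), total)
    return float(acc)


def iter_set_partitions(items):
    """All set partitions via restricted-growth strings."""
    items = list(items)
    n = len(items)
    if n == 0:
        yield []
        return
    rgs = [0] * n
    while True:
        groups: dict[int, list] = {}
        for item, g in zip(items, rgs):
            groups.setdefault(g, []).append(item)
        yield list(groups.values())
        prefix_max = [0] * n  # max of rgs[0..j-1]
        for j in range(1, n):
            prefix_max[j] = max(prefix_max[j - 1], rgs[j - 1])
        i = n - 1
        while i > 0 and rgs[i] > prefix_max[i]:
            i -= 1
        if i == 0:
            return
        rgs[i] += 1
        for j in range(i + 1, n):
            rgs[j] = 0


def potts_energy(und: nx.Graph, groups, gamma: float = 1.0) -> float:
    """Reichardt-Bornholdt energy of a partition given as a list of groups."""
    m = und.number_of_edges()
    if m == 0:
        return 0.0
    deg = dict(und.degree())
    h = 0.0
    for group in groups:
        group = list(group)
        for i, u in enumerate(group):
            for v in group[i + 1 :]:
                a = 1.0 if und.has_edge(u, v) else 0.0
                h -= a - gamma * deg[u] * deg[v] / (2.0 * m)
    return h


def exhaustive_min_energy(und: nx.Graph, gamma: float = 1.0):
    """Global minimum of the Potts energy over all partitions (small graphs)."""
    nodes = list(und.nodes)
    best_h, best_groups = np.inf, None
    for groups in iter_set_partitions(nodes):
        h = potts_energy(und, groups, gamma)
        if h < best_h - 1e-12:
            best_h, best_groups = h, [set(g) for g in groups]
    return best_h, best_groups


def authority_eig(graph: nx.DiGraph):
    """Dominant eigenvector of A^T A by dense symmetric eigendecomposition.

    Returns (scores dict, eigengap ratio). Scores are sign-fixed nonnegative
    and L2-normalized; all-zero when the graph has no edges.
    """
    nodes = sorted(graph.nodes, key=str)
    a = nx.to_numpy_array(graph, nodelist=nodes)
    ata = a.T @ a
    vals, vecs = np.linalg.eigh(ata)
    if vals[-1] <= 0:
        return {u: 0.0 for u in nodes}, np.inf
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.abs(v)  # Perron vector of a nonnegative matrix is nonnegative
    v = v / np.linalg.norm(v)
    gap = (vals[-1] - vals[-2]) / vals[-1] if len(vals) > 1 else np.inf
    return {u: float(v[i]) for i, u in enumerate(nodes)}, gap


def ancestor_walk(graph: nx.DiGraph, term) -> set:
    """Brute-force ancestor set by repeated parent expansion."""
    seen = set()
    frontier = [term]
    while frontier:
        node = frontier.pop()
        for parent in graph.successors(node):
            if parent not in seen:
                seen.add(parent)
                frontier.append(parent)
    return seen


def partitions_equivalent(p1: dict, p2_groups) -> bool:
    """Label-permutation-invariant equality of a node->label map vs groups."""
    groups1 = {}
    for node, lab in p1.items():
        groups1.setdefault(lab, set()).add(node)
    return sorted(map(sorted, groups1.values())) == sorted(
        sorted(g) for g in p2_groups
    )
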