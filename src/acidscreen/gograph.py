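"""Community-level summarization of an enriched-term ontology subgraph.

The subgraph induced by the significant terms plus all their ancestors is
partitioned by minimizing the Reichardt-Bornholdt spin-glass Hamiltonian

    H(sigma) = - sum_{i<j} [A_ij - gamma * k_i k_j / (2m)] * delta(sigma_i, sigma_j)

on the undirected simple view of the graph, by simulated annealing over at
most ``max_spins`` labels (200 by default, matching the configured cap on
possible spin states). Each community is then represented by its member with
the highest HITS authority score — ontology edges run child->parent, so
authority accumulates on general, heavily referenced terms — and the graph is
collapsed onto those representatives, with the significant terms re-attached
as membership leaves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "AnnealSchedule",
    "CollapsedGraph",
    "ancestors",
    "build_subgraph",
    "hamiltonian",
    "spinglass_partition",
    "authority_scores",
    "select_representatives",
    "collapse",
    "export_graphml",
    "export_dot",
]

COMMUNITY_PREFIX = "community:"


def ancestors(term: str, ontology: nx.DiGraph) -> frozenset:
    """All ancestors of a term (transitive closure along child->parent edges).

    Excludes the term itself; the root therefore has no ancestors.
    """
    if term not in ontology:
        raise KeyError(f"unknown term: {term}")
    return frozenset(nx.descendants(ontology, term))


def build_subgraph(significant_terms, ontology: nx.DiGraph) -> nx.DiGraph:
    """Ontology subgraph induced by the significant terms and their ancestors.

    Node attribute ``significant`` flags the original terms; ``name`` is
    carried over from the ontology.
    """
    significant_terms = set(significant_terms)
    if not significant_terms:
        raise ValueError("no significant terms supplied")
    missing = sorted(t for t in significant_terms if t not in ontology)
    if missing:
        raise KeyError(f"terms not in ontology: {missing}")
    nodes = set(significant_terms)
    for t in significant_terms:
        nodes |= ancestors(t, ontology)
    # built node-by-node in sorted order so iteration (and every artifact
    # derived from it) is independent of set/hash ordering
    sub = nx.DiGraph()
    for n in sorted(nodes, key=str):
        sub.add_node(n, **ontology.nodes[n], significant=n in significant_terms)
    for u in sub.nodes:
        for v in sorted(ontology.successors(u), key=str):
            if v in nodes:
                sub.add_edge(u, v)
    return sub


# ---------------------------------------------------------------------------
# spin-glass Potts partitioning


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule; one sweep proposes |V| single-node moves."""

    t_start: float = 1.0
    t_stop: float = 0.01
    cooling: float = 0.99
    sweeps_per_temp: int = 1


def hamiltonian(graph: nx.Graph, partition: dict, gamma: float = 1.0) -> float:
    """Reichardt-Bornholdt Potts energy of a partition.

    Evaluated on the undirected simple view of ``graph``; every node must be
    labeled. Double precision; the all-singleton partition scores exactly 0.
    """
    und = nx.Graph(graph)
    unlabeled = [n for n in und.nodes if n not in partition]
    if unlabeled:
        raise KeyError(f"unlabeled nodes: {sorted(map(str, unlabeled))[:5]}")
    m = und.number_of_edges()
    if m == 0:
        return 0.0
    deg = dict(und.degree())
    nodes = list(und.nodes)
    h = 0.0
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            if partition[u] == partition[v]:
                a = 1.0 if und.has_edge(u, v) else 0.0
                h -= a - gamma * deg[u] * deg[v] / (2.0 * m)
    return h


def _anneal_component(
    und: nx.Graph,
    nodes: list,
    gamma: float,
    max_spins: int,
    rng: np.random.Generator,
    schedule: AnnealSchedule,
    n_restarts: int,
) -> dict:
    """Simulated annealing + greedy descent on one connected component."""
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    adj = [np.array([idx[v] for v in und.neighbors(u)], dtype=np.intp) for u in nodes]
    deg = np.array([len(a) for a in adj], dtype=float)
    m = und.number_of_edges()
    two_m = 2.0 * m
    q = min(n, max_spins)

    def energy_delta(labels, comm_deg, node, new_label):
        """H(after) - H(before) for relabeling one node."""
        old = labels[node]
        if new_label == old:
            return 0.0
        links_old = np.count_nonzero(labels[adj[node]] == old)
        links_new = np.count_nonzero(labels[adj[node]] == new_label)
        k = deg[node]
        null_old = gamma * k * (comm_deg[old] - k) / two_m
        null_new = gamma * k * comm_deg[new_label] / two_m
        # leaving old community removes -(links_old - null_old) from H
        return (links_old - null_old) - (links_new - null_new)

    best_labels = None
    best_h = np.inf
    for _ in range(max(1, n_restarts)):
        labels = rng.integers(0, q, size=n)
        comm_deg = np.zeros(q)
        np.add.at(comm_deg, labels, deg)
        t = schedule.t_start
        while t > schedule.t_stop:
            for _ in range(schedule.sweeps_per_temp * n):
                node = int(rng.integers(n))
                new_label = int(rng.integers(q))
                dh = energy_delta(labels, comm_deg, node, new_label)
                if dh <= 0 or rng.random() < np.exp(-dh / t):
                    comm_deg[labels[node]] -= deg[node]
                    comm_deg[new_label] += deg[node]
                    labels[node] = new_label
            t *= schedule.cooling
        # greedy descent: single-node moves plus whole-community merges (the
        # latter escape the common trap where a merge is downhill overall but
        # every intermediate single move is uphill)
        improved = True
        while improved:
            improved = False
            for node in range(n):
                deltas = np.array(
                    [energy_delta(labels, comm_deg, node, lab) for lab in range(q)]
                )
                lab = int(np.argmin(deltas))
                if deltas[lab] < -1e-12:
                    comm_deg[labels[node]] -= deg[node]
                    comm_deg[lab] += deg[node]
                    labels[node] = lab
                    improved = True
            used = sorted(set(labels.tolist()))
            if len(used) > 1:
                links = np.zeros((q, q))
                for node in range(n):
                    for nb in adj[node]:
                        if nb > node:
                            links[labels[node], labels[nb]] += 1
                links = links + links.T
                for ai, a in enumerate(used):
                    for b in used[ai + 1 :]:
                        dh = -(links[a, b] - gamma * comm_deg[a] * comm_deg[b] / two_m)
                        if dh < -1e-12:
                            labels[labels == a] = b
                            comm_deg[b] += comm_deg[a]
                            comm_deg[a] = 0.0
                            improved = True
                            break
                    else:
                        continue
                    break
        # evaluate H of this restart from the per-pair definition
        part = {u: int(labels[idx[u]]) for u in nodes}
        h = hamiltonian(und.subgraph(nodes), part, gamma)
        if h < best_h - 1e-12:
            best_h = h
            best_labels = labels.copy()
    return {u: int(best_labels[idx[u]]) for u in nodes}


def spinglass_partition(
    graph: nx.Graph,
    gamma: float = 1.0,
    max_spins: int = 200,
    seed: int = 0,
    schedule: AnnealSchedule = AnnealSchedule(),
    n_restarts: int = 5,
) -> dict:
    """Partition a term graph by annealing the spin-glass Hamiltonian.

    Works on the undirected simple view; disconnected graphs are partitioned
    per weakly-connected component with globally distinct labels. Community
    labels are relabeled to consecutive integers starting at 1, ordered by
    each community's smallest node, so the labeling is deterministic for a
    fixed seed.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    und = nx.Graph(graph)
    if und.number_of_edges() == 0:
        warnings.warn("graph has no edges; every node is its own community", stacklevel=2)
        return {u: i + 1 for i, u in enumerate(sorted(und.nodes, key=str))}
    rng = np.random.default_rng(seed)
    raw: dict = {}
    offset = 0
    for comp in sorted(nx.connected_components(und), key=lambda c: sorted(map(str, c))[0]):
        nodes = sorted(comp, key=str)
        if len(nodes) == 1:
            raw[nodes[0]] = offset
            offset += 1
            continue
        comp_part = _anneal_component(
            und.subgraph(nodes), nodes, gamma, max_spins, rng, schedule, n_restarts
        )
        used = sorted(set(comp_part.values()))
        remap = {old: offset + i for i, old in enumerate(used)}
        for u, lab in comp_part.items():
            raw[u] = remap[lab]
        offset += len(used)
    # canonical labels: 1..q ordered by each community's smallest member
    groups: dict[int, list] = {}
    for u, lab in raw.items():
        groups.setdefault(lab, []).append(u)
    ordered = sorted(groups.values(), key=lambda g: sorted(map(str, g))[0])
    return {u: i + 1 for i, grp in enumerate(ordered) for u in grp}


# ---------------------------------------------------------------------------
# HITS authority and collapse


def authority_scores(
    graph: nx.DiGraph, tol: float = 1e-10, max_iter: int = 1000
) -> dict:
    """HITS authority vector by power iteration.

    Iterates a <- A^T h, h <- A a with L2 normalization until the L1 change
    in the authority vector falls below ``tol``; the fixed point is the
    dominant eigenvector of A^T A (nonnegative, unit L2 norm). An edgeless
    graph scores 0 everywhere.
    """
    nodes = sorted(graph.nodes, key=str)
    n = len(nodes)
    if n == 0:
        return {}
    a_mat = nx.to_numpy_array(nx.DiGraph(graph), nodelist=nodes)
    if a_mat.sum() == 0:
        return {u: 0.0 for u in nodes}
    h = np.ones(n)
    auth = np.zeros(n)
    for _ in range(max_iter):
        new_auth = a_mat.T @ h
        norm = np.linalg.norm(new_auth)
        if norm > 0:
            new_auth = new_auth / norm
        h = a_mat @ new_auth
        hnorm = np.linalg.norm(h)
        if hnorm > 0:
            h = h / hnorm
        residual = float(np.abs(new_auth - auth).sum())
        auth = new_auth
        if residual < tol:
            return {u: float(auth[i]) for i, u in enumerate(nodes)}
    raise RuntimeError(
        f"HITS failed to converge in {max_iter} iterations (L1 residual {residual:.3g})"
    )


def select_representatives(partition: dict, scores: dict, seed: int = 0) -> dict:
    """Pick each community's maximal-authority member; random exact-tie break.

    The tie-break RNG stream is derived from (seed, community label) so that
    adding or removing one community never perturbs the others' choices;
    fixed seed implies a fixed choice.
    """
    missing = [u for u in partition if u not in scores]
    if missing:
        raise KeyError(f"nodes without authority scores: {sorted(map(str, missing))[:5]}")
    communities: dict[int, list] = {}
    for u, lab in partition.items():
        communities.setdefault(lab, []).append(u)
    reps = {}
    for lab, members in communities.items():
        members = sorted(members, key=str)
        best = max(scores[u] for u in members)
        tied = [u for u in members if scores[u] == best]
        if len(tied) == 1:
            reps[lab] = tied[0]
        else:
            rng = np.random.default_rng([seed, lab])
            reps[lab] = tied[int(rng.integers(len(tied)))]
    return reps


@dataclass
class CollapsedGraph:
    """Community-level summary graph.

    ``graph`` holds one node per community (id ``community:<label>``, with
    representative term, member count and color index) plus one leaf node per
    significant term; edges are either directed ``inter_community`` edges
    inherited from the contracted term graph or ``membership`` edges linking
    each significant term to its community.
    """

    graph: nx.DiGraph
    representatives: dict
    member_counts: dict

    @property
    def community_nodes(self) -> list:
        return [
            n for n, d in self.graph.nodes(data=True) if d["kind"] == "community"
        ]

    @property
    def term_nodes(self) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "term"]


def collapse(
    graph: nx.DiGraph,
    partition: dict,
    reps: dict,
    significant_terms,
    edge_mode: str = "contracted",
    ontology: nx.DiGraph | None = None,
) -> CollapsedGraph:
    """Contract each community onto its representative and re-attach terms.

    Stage 1 contracts every community into a single community node carrying
    its representative term; cross-community edges are kept with direction,
    deduplicated, and self-loops removed. Stage 2 re-attaches every
    significant term as a leaf with a single membership edge to its
    community node.

    ``edge_mode='contracted'`` (default) derives inter-community edges from
    the contracted member edges; ``edge_mode='rep-ancestry'`` draws an edge
    between two community nodes only when one representative is an ancestor
    of the other in the full ontology (requires ``ontology``).
    """
    for lab, rep in reps.items():
        if partition.get(rep) != lab:
            raise ValueError(f"representative {rep} is not a member of community {lab}")
    labels = set(partition.values())
    if set(reps) != labels:
        raise ValueError("representatives must cover every community")

    counts: dict[int, int] = {}
    for u in graph.nodes:
        counts[partition[u]] = counts.get(partition[u], 0) + 1

    out = nx.DiGraph()
    for i, lab in enumerate(sorted(labels)):
        rep = reps[lab]
        out.add_node(
            f"{COMMUNITY_PREFIX}{lab}",
            kind="community",
            representative=rep,
            representative_name=str(graph.nodes[rep].get("name", rep)),
            member_count=counts[lab],
            color_index=i,
        )
    if edge_mode == "contracted":
        for u, v in graph.edges:
            cu, cv = partition[u], partition[v]
            if cu != cv:
                out.add_edge(
                    f"{COMMUNITY_PREFIX}{cu}", f"{COMMUNITY_PREFIX}{cv}", kind="inter_community"
                )
    elif edge_mode == "rep-ancestry":
        if ontology is None:
            raise ValueError("edge_mode='rep-ancestry' requires the ontology")
        labs = sorted(labels)
        for a in labs:
            for b in labs:
                if a != b and reps[b] in ancestors(reps[a], ontology):
                    out.add_edge(
                        f"{COMMUNITY_PREFIX}{a}", f"{COMMUNITY_PREFIX}{b}", kind="inter_community"
                    )
    else:
        raise ValueError(f"unknown edge_mode: {edge_mode!r}")

    for term in sorted(set(significant_terms), key=str):
        if term not in partition:
            raise KeyError(f"significant term {term} not in the partitioned graph")
        out.add_node(
            term,
            kind="term",
            name=str(graph.nodes[term].get("name", term)),
            community=int(partition[term]),
        )
        out.add_edge(term, f"{COMMUNITY_PREFIX}{partition[term]}", kind="membership")
    return CollapsedGraph(graph=out, representatives=dict(reps), member_counts=counts)


def export_graphml(collapsed: CollapsedGraph, path) -> None:
    """Write the collapsed graph as GraphML (attributes preserved)."""
    nx.write_graphml(collapsed.graph, path)


def export_dot(collapsed: CollapsedGraph, path) -> None:
    """Write the collapsed graph as a simple Graphviz DOT file."""
    g = collapsed.graph
    with open(path, "w") as fh:
        fh.write("digraph collapsed {\n")
        for n, d in sorted(g.nodes(data=True), key=lambda x: str(x[0])):
            if d["kind"] == "community":
                label = f"{d['representative_name']} (n={d['member_count']})"
                fh.write(f'  "{n}" [shape=ellipse, kind=community, label="{label}"];\n')
            else:
                fh.write(f'  "{n}" [shape=point, kind=term, label="{d["name"]}"];\n')
        for u, v, d in sorted(g.edges(data=True), key=lambda x: (str(x[0]), str(x[1]))):
            style = "solid" if d["kind"] == "inter_community" else "dashed"
            fh.write(f'  "{u}" -> "{v}" [kind={d["kind"]}, style={style}];\n')
        fh.write("}\n")
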