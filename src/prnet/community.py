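"""Community detection by short random walks (walktrap).

The weighted network is decomposed agglomeratively following Pons & Latapy's
walktrap procedure. A t-step random walk started at node i visits node k with
probability ``P^t_ik``, where the one-step transition probability is the edge
weight divided by the weighted degree of the source. Nodes whose walks land in
similar places are structurally close; the node-node distance is

    r_ij = sqrt( sum_k (P^t_ik - P^t_jk)^2 / d(k) )

with d(k) the weighted degree. Starting from singleton communities, the pair
of *adjacent* (edge-connected) communities whose merge minimally increases the
mean squared distance,

    delta_sigma(C1, C2) = (1/n) * |C1||C2| / (|C1|+|C2|) * r^2_{C1,C2},

is merged repeatedly; a community's walk distribution is the average of its
members'. Distances to a freshly merged community are obtained by the
Ward-style Lance-Williams update when both constituent distances are known,
and directly from the averaged distributions otherwise. Modularity is recorded
after every merge and the dendrogram is cut at the merge prefix with maximum
modularity (the initial singleton partition included).

Because only adjacent communities ever merge, no community can span two
connected components. Ties in delta_sigma are broken by the smallest
community-id pair, making the procedure fully deterministic for a given node
insertion order.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .coexpression import WeightedNetwork
from .exceptions import InputError

log = logging.getLogger("prnet")


@dataclass(frozen=True)
class WalktrapParams:
    """Random-walk length t (>= 1). Default 4, the customary walktrap default."""

    steps: int = 4

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise InputError(f"walk steps must be >= 1, got {self.steps}")


@dataclass
class CommunityPartition:
    """Result of the agglomerative decomposition.

    ``assignment`` maps each gene to a community id (0-based, numbered by the
    smallest node position in each community). ``merge_sequence`` holds the
    full dendrogram as (community-a, community-b, new-community) triples in
    internal id space (leaves are 0..n-1 in node order); ``modularity_trace``
    holds modularity before any merge and after each merge, so
    ``modularity_trace[k]`` scores the partition after k merges.
    """

    assignment: dict[str, int]
    merge_sequence: list[tuple[int, int, int]] = field(default_factory=list)
    modularity_trace: list[float] = field(default_factory=list)
    best_modularity: float = 0.0

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def communities(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for gene, cid in self.assignment.items():
            out.setdefault(cid, set()).add(gene)
        return out


def _as_graph(network) -> nx.Graph:
    return network.graph if isinstance(network, WeightedNetwork) else network


def transition_probabilities(network, steps: int = 4):
    """t-step random-walk distributions for every node.

    Returns ``(nodes, Pt)`` where row i of ``Pt`` is the distribution of a
    t-step walk started at ``nodes[i]``; each row sums to 1.
    """
    G = _as_graph(network)
    nodes = list(G.nodes)
    if not nodes:
        raise InputError("transition_probabilities: empty network")
    W = nx.to_numpy_array(G, nodelist=nodes, weight="weight")
    d = W.sum(axis=1)
    if np.any(d <= 0):
        bad = [nodes[i] for i in np.flatnonzero(d <= 0)]
        raise InputError(f"isolated node(s) with zero degree: {bad[:5]}")
    P = W / d[:, None]
    Pt = np.linalg.matrix_power(P, steps)
    return nodes, Pt


def delta_sigma(dist_a: np.ndarray, dist_b: np.ndarray, inv_degree: np.ndarray,
                size_a: int, size_b: int, n: int) -> float:
    """Mean squared-distance increase for merging two communities.

    ``dist_a``/``dist_b`` are the communities' averaged t-step walk
    distributions. Exposed separately so tests can recompute every distance
    from first principles and compare with the incremental updates.
    """
    diff = dist_a - dist_b
    r2 = float(np.einsum("k,k,k->", diff, diff, inv_degree))
    return (size_a * size_b) / (size_a + size_b) / n * r2


def modularity(network, assignment: dict[str, int]) -> float:
    """Weighted Newman modularity Q = sum_c (e_c - a_c^2).

    ``e_c`` is the fraction of total edge weight inside community c and
    ``a_c`` the fraction of total weighted degree incident to c.
    """
    G = _as_graph(network)
    missing = [v for v in G.nodes if v not in assignment]
    if missing:
        raise InputError(f"assignment missing node(s): {sorted(missing)[:5]}")
    m = G.size(weight="weight")
    if m <= 0:
        raise InputError("modularity undefined for a network with no edges")
    e: dict[int, float] = {}
    a: dict[int, float] = {}
    for u, v, w in G.edges(data="weight", default=1.0):
        cu, cv = assignment[u], assignment[v]
        if cu == cv:
            e[cu] = e.get(cu, 0.0) + w
        a[cu] = a.get(cu, 0.0) + w
        a[cv] = a.get(cv, 0.0) + w
    return sum(e.get(c, 0.0) / m - (a[c] / (2.0 * m)) ** 2 for c in a)


def walktrap(network, params: WalktrapParams | None = None) -> CommunityPartition:
    """Decompose a weighted network into communities by short random walks.

    Returns the dendrogram cut (merge prefix) of maximum modularity. Isolated
    nodes, for which the walk is undefined, are removed and reported; the
    weighted-network constructor never produces them in the normal pipeline.
    """
    params = params or WalktrapParams()
    G = _as_graph(network)
    if G.number_of_nodes() == 0:
        raise InputError("walktrap: empty network")
    isolated = [v for v in G.nodes if G.degree(v) == 0]
    if isolated:
        log.warning("walktrap: removing %d isolated node(s)", len(isolated))
        G = G.subgraph([v for v in G.nodes if G.degree(v) > 0]).copy()
        if G.number_of_nodes() == 0:
            raise InputError("walktrap: network has only isolated nodes")

    nodes = list(G.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    W = nx.to_numpy_array(G, nodelist=nodes, weight="weight")
    degree = W.sum(axis=1)
    inv_degree = 1.0 / degree
    m_total = W.sum() / 2.0
    Pt = np.linalg.matrix_power(W / degree[:, None], params.steps)

    # per-community state, keyed by internal id (leaves 0..n-1)
    size = {i: 1 for i in range(n)}
    dist = {i: Pt[i] for i in range(n)}
    w_in = {i: 0.0 for i in range(n)}          # intra-community weight
    strength = {i: float(degree[i]) for i in range(n)}
    nbrs: dict[int, set[int]] = {i: set() for i in range(n)}
    cross: dict[tuple[int, int], float] = {}   # inter-community weight
    for u, v, w in G.edges(data="weight", default=1.0):
        i, j = index[u], index[v]
        key = (i, j) if i < j else (j, i)
        cross[key] = cross.get(key, 0.0) + w
        nbrs[i].add(j)
        nbrs[j].add(i)

    dsig: dict[tuple[int, int], float] = {}
    heap: list[tuple[float, int, int]] = []
    for (i, j) in cross:
        ds = delta_sigma(dist[i], dist[j], inv_degree, 1, 1, n)
        dsig[(i, j)] = ds
        heap.append((ds, i, j))
    heapq.heapify(heap)

    active = set(range(n))

    def q_current() -> float:
        return sum(w_in[c] / m_total - (strength[c] / (2.0 * m_total)) ** 2
                   for c in active)

    trace = [q_current()]
    merges: list[tuple[int, int, int]] = []
    next_id = n

    while heap:
        ds, a, b = heapq.heappop(heap)
        key_ab = (a, b)
        if a not in active or b not in active or key_ab not in dsig:
            continue
        ds_ab = dsig[key_ab]
        c = next_id
        next_id += 1
        sa, sb = size[a], size[b]
        size[c] = sa + sb
        dist[c] = (sa * dist[a] + sb * dist[b]) / (sa + sb)
        w_in[c] = w_in[a] + w_in[b] + cross.pop(key_ab)
        strength[c] = strength[a] + strength[b]
        del dsig[key_ab]

        new_nbrs = (nbrs[a] | nbrs[b]) - {a, b}
        for x in sorted(new_nbrs):
            ka = (a, x) if a < x else (x, a)
            kb = (b, x) if b < x else (x, b)
            cw = cross.pop(ka, 0.0) + cross.pop(kb, 0.0)
            cross[(x, c)] = cw
            nbrs[x].discard(a)
            nbrs[x].discard(b)
            nbrs[x].add(c)
            da = dsig.pop(ka, None)
            db = dsig.pop(kb, None)
            if da is not None and db is not None:
                sx = size[x]
                ds_new = ((sa + sx) * da + (sb + sx) * db - sx * ds_ab) \
                    / (sa + sb + sx)
            else:
                ds_new = delta_sigma(dist[c], dist[x], inv_degree,
                                     size[c], size[x], n)
            dsig[(x, c)] = ds_new
            heapq.heappush(heap, (ds_new, x, c))

        nbrs[c] = new_nbrs
        for old in (a, b):
            active.discard(old)
            del dist[old], nbrs[old]
        active.add(c)
        merges.append((a, b, c))
        trace.append(q_current())

    best_idx = max(range(len(trace)), key=trace.__getitem__)
    best_q = trace[best_idx]

    # replay the winning merge prefix to recover community membership
    promoted: dict[int, int] = {}
    for a, b, c in merges[:best_idx]:
        promoted[a] = c
        promoted[b] = c

    def find(i: int) -> int:
        while i in promoted:
            i = promoted[i]
        return i

    renumber: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for i, v in enumerate(nodes):
        root = find(i)
        if root not in renumber:
            renumber[root] = len(renumber)
        assignment[v] = renumber[root]

    log.info(
        "walktrap: %d nodes, %d merges, best modularity %.6f at %d communities",
        n, len(merges), best_q, len(renumber),
    )
    return CommunityPartition(
        assignment=assignment,
        merge_sequence=merges,
        modularity_trace=trace,
        best_modularity=best_q,
    )


def cut_assignment(network, merge_sequence: list[tuple[int, int, int]],
                   n_merges: int) -> dict[str, int]:
    """Partition obtained by applying the first ``n_merges`` dendrogram merges.

    Utility for inspecting alternative cuts; ids are renumbered 0-based by
    smallest node position, matching :func:`walktrap` output.
    """
    G = _as_graph(network)
    nodes = [v for v in G.nodes if G.degree(v) > 0]
    promoted: dict[int, int] = {}
    for a, b, c in merge_sequence[:n_merges]:
        promoted[a] = c
        promoted[b] = c

    def find(i: int) -> int:
        while i in promoted:
            i = promoted[i]
        return i

    renumber: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for i, v in enumerate(nodes):
        root = find(i)
        if root not in renumber:
            renumber[root] = len(renumber)
        assignment[v] = renumber[root]
    return assignment
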