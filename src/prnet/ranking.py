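"""Disease-specific network construction and PageRank gene scoring.

Communities that contain at least one known cancer-associated gene (CAG) form
the disease-specific network; all other communities are discarded. Every gene
of the retained communities — seeds included — is then scored by PageRank on
the induced subgraph:

    PR(i) = (1 - q)/N + q * sum_{j ~ i} PR(j) / L(j)

with damping factor q (default 0.85), N the number of scored genes, and L(j)
the number of links of neighbour j. The recurrence is degree-based, so the
unweighted walk is the default; ``weighted=True`` substitutes the
strength-normalised analogue PR(j) * w_ij / strength(j). The induced graph may
be disconnected (it is a union of communities); the teleportation term keeps
the iteration ergodic, and degree-zero nodes redistribute their mass uniformly
over all nodes. One global PageRank run keeps scores comparable across
communities; a per-community mode exists for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .coexpression import WeightedNetwork
from .community import CommunityPartition
from .exceptions import ConvergenceError, InputError
from .net_io import GeneSet

log = logging.getLogger("prnet")


@dataclass(frozen=True)
class PageRankParams:
    q: float = 0.85
    tol: float = 1e-10
    max_iter: int = 1000
    weighted: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise InputError(f"damping factor q must be in (0, 1), got {self.q}")
        if self.tol <= 0 or self.max_iter < 1:
            raise InputError("tol must be > 0 and max_iter >= 1")


@dataclass
class DiseaseNetwork:
    """Union of CAG-containing communities with its induced edges."""

    graph: nx.Graph
    retained_communities: frozenset[int]
    assignment: dict[str, int]
    cag_hits: dict[int, frozenset[str]]

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)


@dataclass(frozen=True)
class RankEntry:
    gene: str
    pagerank: float
    rank: int
    community_id: int


@dataclass
class GeneRanking:
    """Genes ordered by decreasing PageRank; ties broken lexicographically."""

    entries: list[RankEntry]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    def as_dict(self) -> dict[str, float]:
        return {e.gene: e.pagerank for e in self.entries}

    def rank_of(self, gene: str) -> int:
        for e in self.entries:
            if e.gene == gene:
                return e.rank
        raise KeyError(gene)


def filter_communities(partition: CommunityPartition, network: WeightedNetwork,
                       cags: GeneSet) -> DiseaseNetwork:
    """Retain exactly the communities that intersect the CAG seed set."""
    members = partition.communities()
    uncovered = [v for v in network.graph.nodes if v not in partition.assignment]
    if uncovered:
        raise InputError(
            f"partition does not cover network node(s): {sorted(uncovered)[:5]}"
        )
    cag_hits = {
        cid: frozenset(genes & cags.symbols)
        for cid, genes in members.items()
        if genes & cags.symbols
    }
    matched = set().union(*cag_hits.values()) if cag_hits else set()
    log.info(
        "filter_communities: %d communities, %d retained "
        "(%d of %d CAG symbols matched)",
        len(members), len(cag_hits), len(matched), len(cags),
    )
    if not cag_hits:
        raise InputError(
            "no community contains a seed gene; check that seed symbols use "
            "the same namespace/case as the network genes"
        )
    node_set = set().union(*(members[cid] for cid in cag_hits))
    induced = network.graph.subgraph(node_set).copy()
    return DiseaseNetwork(
        graph=induced,
        retained_communities=frozenset(cag_hits),
        assignment={g: partition.assignment[g] for g in node_set},
        cag_hits=cag_hits,
    )


@dataclass
class PageRankResult:
    scores: dict[str, float]
    n_iter: int
    residual: float


def power_iteration(graph: nx.Graph, params: PageRankParams) -> PageRankResult:
    """Iterate the PageRank recurrence on an undirected graph to convergence.

    Each undirected edge acts as two directed links. Degree-zero (dangling)
    nodes distribute their mass uniformly to all nodes. Stops when the L1
    change of the score vector falls below ``tol``.
    """
    nodes = sorted(graph.nodes)
    N = len(nodes)
    if N == 0:
        raise InputError("pagerank: empty node set")
    index = {v: i for i, v in enumerate(nodes)}

    rows, cols, vals = [], [], []
    weight_key = "weight" if params.weighted else None
    out = np.zeros(N)
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0)) if params.weighted else 1.0
        i, j = index[u], index[v]
        out[i] += w
        out[j] += w
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0)) if params.weighted else 1.0
        i, j = index[u], index[v]
        if out[j] > 0:
            rows.append(i); cols.append(j); vals.append(w / out[j])
        if out[i] > 0:
            rows.append(j); cols.append(i); vals.append(w / out[i])
    M = sp.csr_matrix((vals, (rows, cols)), shape=(N, N))
    dangling = out == 0.0

    q = params.q
    p = np.full(N, 1.0 / N)
    for it in range(1, params.max_iter + 1):
        p_new = q * (M @ p) + q * p[dangling].sum() / N + (1.0 - q) / N
        residual = float(np.abs(p_new - p).sum())
        p = p_new
        if residual < params.tol:
            log.info("pagerank: converged in %d iterations (residual %.3g)",
                     it, residual)
            return PageRankResult({v: float(p[index[v]]) for v in nodes},
                                  it, residual)
    raise ConvergenceError(
        f"pagerank did not converge in {params.max_iter} iterations "
        f"(residual {residual:.3g}, tol {params.tol:.3g})"
    )


def pagerank(dnet: DiseaseNetwork | nx.Graph,
             params: PageRankParams | None = None) -> dict[str, float]:
    """PageRank scores for every gene of the disease-specific network."""
    params = params or PageRankParams()
    graph = dnet.graph if isinstance(dnet, DiseaseNetwork) else dnet
    return power_iteration(graph, params).scores


def pagerank_per_community(dnet: DiseaseNetwork,
                           params: PageRankParams | None = None
                           ) -> dict[int, dict[str, float]]:
    """Comparison mode: run PageRank separately inside each retained community.

    Each run normalises to 1 over its own community, so scores are not
    comparable across communities of different sizes.
    """
    params = params or PageRankParams()
    members: dict[int, set[str]] = {}
    for gene, cid in dnet.assignment.items():
        members.setdefault(cid, set()).add(gene)
    out: dict[int, dict[str, float]] = {}
    for cid in sorted(members):
        sub = dnet.graph.subgraph(members[cid]).copy()
        out[cid] = power_iteration(sub, params).scores
    return out


def rank_genes(scores: dict[str, float], dnet: DiseaseNetwork) -> GeneRanking:
    """Order genes by decreasing PageRank; ties break by gene symbol."""
    missing = [g for g in dnet.node_set if g not in scores]
    if missing:
        raise InputError(f"scores missing for gene(s): {sorted(missing)[:5]}")
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    entries = [
        RankEntry(gene=g, pagerank=s, rank=i + 1,
                  community_id=dnet.assignment[g])
        for i, (g, s) in enumerate(ordered)
    ]
    return GeneRanking(entries)
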