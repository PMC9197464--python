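"""Co-expression weighting of protein-protein interaction edges.

Each PPI edge (A, B) is annotated with the correlation of the two genes'
expression profiles across samples, W(A,B) = corr(A,B); pairs without a PPI
edge are never scored. The signed correlation is preserved on every edge, but
the edge *weight* used by the downstream random-walk community detection and
PageRank steps is its absolute value: both algorithms require non-negative
weights, and strong negative co-expression is still functional association.

Expression is first filtered (genes expressed in too few samples are removed)
and log2(x+1)-transformed; correlations default to Pearson on the transformed
values, with Spearman available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import InputError
from .net_io import EdgeList, ExpressionMatrix

log = logging.getLogger("prnet")

_METHODS = ("pearson", "spearman")


@dataclass
class WeightedNetwork:
    """PPI network with per-edge co-expression weights.

    Edge attributes: ``signed_corr`` in [-1, 1] and ``weight`` = |signed_corr|
    in [0, 1]. Nodes without any surviving edge are absent; the edge set is
    always a subset of the input PPI edge list.
    """

    graph: nx.Graph
    weight_mode: str = "abs_pearson"

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_weight(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["weight"]


def preprocess_expression(expr: ExpressionMatrix,
                          min_nonzero_fraction: float = 0.5) -> ExpressionMatrix:
    """Filter sparsely expressed genes and apply log2(x+1).

    Genes with nonzero values in fewer than ``min_nonzero_fraction`` of
    samples are removed (default 0.5: zero expression in more than half of
    the samples).
    """
    if expr.transformed:
        raise InputError("expression matrix is already log-transformed")
    if not 0.0 <= min_nonzero_fraction <= 1.0:
        raise InputError(f"min_nonzero_fraction must be in [0, 1], "
                         f"got {min_nonzero_fraction}")
    values = expr.values
    n_samples = values.shape[1]
    keep = (values != 0).sum(axis=1) >= min_nonzero_fraction * n_samples
    n_removed = int((~keep).sum())
    if not keep.any():
        raise InputError("all genes removed by the expression filter")
    filtered = expr.data.loc[keep]
    transformed = pd.DataFrame(
        np.log2(filtered.to_numpy() + 1.0),
        index=filtered.index, columns=filtered.columns,
    )
    log.info(
        "preprocess_expression: %d of %d genes removed "
        "(nonzero fraction < %.3g), %d retained",
        n_removed, len(keep), min_nonzero_fraction, int(keep.sum()),
    )
    return ExpressionMatrix(transformed, transformed=True)


def correlation(x, y, method: str = "pearson") -> float:
    """Sample correlation of two equal-length vectors.

    Returns NaN (the undefined marker) when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise InputError("correlation requires 1-d vectors of length >= 3")
    if method not in _METHODS:
        raise InputError(f"unknown correlation method {method!r}")
    if method == "spearman":
        x = rankdata(x)
        y = rankdata(y)
    xc = x - x.mean()
    yc = y - y.mean()
    nx_ = np.sqrt(xc @ xc)
    ny_ = np.sqrt(yc @ yc)
    if nx_ == 0.0 or ny_ == 0.0:
        return float("nan")
    return float(np.clip((xc @ yc) / (nx_ * ny_), -1.0, 1.0))


def weight_network(expr: ExpressionMatrix, ppi: EdgeList,
                   method: str = "pearson",
                   min_abs_corr: float = 0.0) -> WeightedNetwork:
    """Attach co-expression weights to the PPI edges.

    An edge survives when both endpoint genes are rows of ``expr``, both have
    nonzero expression variance, and |corr| >= ``min_abs_corr``. Dropped edge
    counts are logged per cause. Correlations are computed only for
    PPI-supported pairs; no other pair is ever emitted.
    """
    if not expr.transformed:
        raise InputError("weight_network expects log-transformed expression "
                         "(run preprocess_expression first)")
    if method not in _METHODS:
        raise InputError(f"unknown correlation method {method!r}")
    if not 0.0 <= min_abs_corr <= 1.0:
        raise InputError(f"min_abs_corr must be in [0, 1], got {min_abs_corr}")

    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    values = expr.values.astype(float)
    if method == "spearman":
        values = rankdata(values, axis=1)
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", centered, centered))
    nonzero_var = norms > 0.0
    # unit-norm rows; zero-variance rows stay zero and are masked below
    scaled = np.divide(centered, norms[:, None],
                       out=np.zeros_like(centered), where=norms[:, None] > 0)

    edges = sorted(ppi.edges)
    present = np.array([a in gene_index and b in gene_index for a, b in edges])
    n_missing = int((~present).sum())

    ia = np.array([gene_index[a] for (a, b), p in zip(edges, present) if p],
                  dtype=int)
    ib = np.array([gene_index[b] for (a, b), p in zip(edges, present) if p],
                  dtype=int)
    kept_pairs = [e for e, p in zip(edges, present) if p]

    G = nx.Graph()
    n_zero_var = n_below = 0
    if len(kept_pairs):
        corr = np.einsum("ij,ij->i", scaled[ia], scaled[ib])
        corr = np.clip(corr, -1.0, 1.0)
        defined = nonzero_var[ia] & nonzero_var[ib]
        n_zero_var = int((~defined).sum())
        strong = np.abs(corr) >= min_abs_corr
        n_below = int((defined & ~strong).sum())
        for (a, b), r, ok in zip(kept_pairs, corr, defined & strong):
            if ok:
                G.add_edge(a, b, signed_corr=float(r), weight=float(abs(r)))

    log.info(
        "weight_network: %d PPI edges -> %d weighted (%d missing expression, "
        "%d zero variance, %d below |corr| threshold %.3g)",
        len(edges), G.number_of_edges(), n_missing, n_zero_var, n_below,
        min_abs_corr,
    )
    if G.number_of_edges() == 0:
        raise InputError("no PPI edge survived co-expression weighting; "
                         "check that gene symbols match between inputs")
    mode = "abs_spearman" if method == "spearman" else "abs_pearson"
    return WeightedNetwork(graph=G, weight_mode=mode)
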