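"""Readers, writers and validated containers for pipeline inputs and outputs.

The pipeline consumes three kinds of input: undirected protein-protein
interaction (PPI) edge lists, a gene-by-sample expression matrix, and a seed
list of known disease genes (cancer-associated genes, CAGs). Gene identity is
the case-sensitive symbol string everywhere; no alias mapping is attempted.
Symbols that fail to match across inputs are counted and logged downstream,
never silently remapped.

File formats are deliberately minimal and text-only:

* edge list — TSV with gene symbols in the first two columns (extra columns
  such as confidence scores or PubMed ids are ignored), optional header;
* expression — TSV, genes in rows (first column), samples in columns
  (header row of sample ids), numeric cells;
* gene set — plain text, one symbol per line, blank lines ignored;
* ranking — TSV with columns rank, gene, pagerank, community_id;
* community table — TSV with columns gene, community_id, retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError

if TYPE_CHECKING:  # pragma: no cover
    from .ranking import GeneRanking

log = logging.getLogger("prnet")


def _canon(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) form of an unordered gene pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class EdgeList:
    """Deduplicated, undirected gene-pair interactions.

    Edges are stored as canonically ordered 2-tuples ``(a, b)`` with
    ``a < b``; self-pairs are never present, and ``(A, B)``/``(B, A)``
    collapse to a single edge.
    """

    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise InputError(f"self-pair {a!r} in edge list")
            if a > b:
                raise InputError(f"non-canonical pair ({a!r}, {b!r})")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "EdgeList":
        """Build an EdgeList, dropping self-pairs and collapsing duplicates."""
        return cls(frozenset(_canon(a, b) for a, b in pairs if a != b))

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(g for e in self.edges for g in e)

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return _canon(a, b) in self.edges


@dataclass
class ExpressionMatrix:
    """Gene x sample numeric matrix used for co-expression.

    ``transformed`` marks whether log2(x+1) has been applied; raw input
    matrices must be non-negative and finite throughout.
    """

    data: pd.DataFrame
    transformed: bool = False

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dups = sorted(set(idx[idx.duplicated()]))
            raise InputError(f"duplicate gene rows: {', '.join(map(str, dups))}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise InputError("expression matrix contains non-numeric values")
        if not np.all(np.isfinite(values)):
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise InputError(
                f"non-finite expression value at gene {idx[g]!r}, "
                f"sample {self.data.columns[s]!r}"
            )
        if not self.transformed and (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise InputError(
                f"negative expression value at gene {idx[g]!r}, "
                f"sample {self.data.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class GeneSet:
    """A set of gene symbols with a free-text role tag (e.g. ``"CAG"``)."""

    symbols: frozenset[str]
    label: str = ""

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, gene: str) -> bool:
        return gene in self.symbols

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.symbols))


# ---------------------------------------------------------------------------
# readers


def read_edge_list(path: str | Path, has_header: bool = False) -> EdgeList:
    """Read a 2+-column TSV of undirected interactions.

    Self-pairs are dropped and symmetric/duplicate rows collapsed; counts of
    rows read, self-loops removed and duplicates collapsed are logged.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"edge list file not found: {path}")
    edges: set[tuple[str, str]] = set()
    rows = self_loops = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 and has_header:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise InputError(
                    f"{path}: line {lineno}: expected >=2 tab-separated columns"
                )
            a, b = parts[0].strip(), parts[1].strip()
            rows += 1
            if a == b:
                self_loops += 1
                continue
            edges.add(_canon(a, b))
    duplicates = rows - self_loops - len(edges)
    log.info(
        "read_edge_list %s: %d rows, %d self-loops removed, "
        "%d duplicates collapsed, %d edges",
        path.name, rows, self_loops, duplicates, len(edges),
    )
    return EdgeList(frozenset(edges))


def merge_edge_lists(lists: Sequence[EdgeList]) -> EdgeList:
    """Union of edge lists under unordered-pair equality."""
    if not lists:
        raise InputError("merge_edge_lists requires at least one input list")
    merged: set[tuple[str, str]] = set()
    for el in lists:
        merged |= el.edges
    total = sum(len(el) for el in lists)
    log.info(
        "merge_edge_lists: %d lists, %d input edges, %d after deduplication "
        "(%d duplicate pairs removed)",
        len(lists), total, len(merged), total - len(merged),
    )
    return EdgeList(frozenset(merged))


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes-in-rows expression TSV with full cell validation."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"expression file not found: {path}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise InputError(f"{path}: empty expression matrix")
    if raw.index.has_duplicates:
        dups = sorted(set(raw.index[raw.index.duplicated()]))
        raise InputError(
            f"{path}: duplicate gene rows: {', '.join(map(str, dups))}"
        )
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise InputError(
            f"{path}: non-numeric value {raw.iat[g, s]!r} at gene "
            f"{raw.index[g]!r}, sample {raw.columns[s]!r}"
        )
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    log.info("read_expression %s: %d genes x %d samples", path.name, *numeric.shape)
    return ExpressionMatrix(numeric, transformed=False)


def read_gene_set(path: str | Path, label: str = "") -> GeneSet:
    """Read a one-symbol-per-line gene list; duplicates collapse with a warning."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"gene set file not found: {path}")
    symbols: list[str] = []
    with path.open() as fh:
        for line in fh:
            sym = line.strip()
            if sym:
                symbols.append(sym)
    unique = frozenset(symbols)
    if not unique:
        raise InputError(f"{path}: gene set file is empty")
    if len(unique) < len(symbols):
        log.warning(
            "read_gene_set %s: %d duplicate symbols collapsed",
            path.name, len(symbols) - len(unique),
        )
    log.info("read_gene_set %s: %d symbols (%s)", path.name, len(unique), label)
    return GeneSet(unique, label=label)


# ---------------------------------------------------------------------------
# writers


def write_edge_list(edge_list: EdgeList, path: str | Path) -> None:
    """Write edges as a sorted 2-column TSV (no header)."""
    with Path(path).open("w") as fh:
        for a, b in sorted(edge_list.edges):
            fh.write(f"{a}\t{b}\n")


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", float_format="%.6g")


def write_gene_set(genes: GeneSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sym in sorted(genes.symbols):
            fh.write(sym + "\n")


def write_ranking(ranking: "GeneRanking", path: str | Path) -> None:
    """Write a ranking TSV sorted by rank; PageRank with 12 significant digits."""
    try:
        fh = Path(path).open("w")
    except OSError as exc:
        raise InputError(f"cannot write ranking to {path}: {exc}") from exc
    with fh:
        fh.write("rank\tgene\tpagerank\tcommunity_id\n")
        for entry in ranking.entries:
            fh.write(
                f"{entry.rank}\t{entry.gene}\t{entry.pagerank:.12g}"
                f"\t{entry.community_id}\n"
            )


def read_ranking(path: str | Path) -> "GeneRanking":
    """Read back a ranking TSV written by :func:`write_ranking`."""
    from .ranking import GeneRanking, RankEntry

    path = Path(path)
    if not path.is_file():
        raise InputError(f"ranking file not found: {path}")
    entries = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["rank", "gene", "pagerank", "community_id"]:
            raise InputError(f"{path}: unexpected ranking header {header!r}")
        for line in fh:
            rank, gene, pr, cid = line.rstrip("\n").split("\t")
            entries.append(RankEntry(gene=gene, pagerank=float(pr),
                                     rank=int(rank), community_id=int(cid)))
    return GeneRanking(entries)


def write_communities(assignment: dict[str, int], retained: Iterable[int],
                      path: str | Path) -> None:
    """Write the community table: gene, community_id, retained flag (0/1)."""
    retained = set(retained)
    with Path(path).open("w") as fh:
        fh.write("gene\tcommunity_id\tretained\n")
        for gene in sorted(assignment):
            cid = assignment[gene]
            fh.write(f"{gene}\t{cid}\t{int(cid in retained)}\n")


def write_weighted_network(network, path: str | Path) -> None:
    """Write a weighted network as 4-column TSV: geneA, geneB, signed_corr, weight."""
    with Path(path).open("w") as fh:
        fh.write("geneA\tgeneB\tsigned_corr\tweight\n")
        rows = sorted(
            (_canon(a, b) + (d["signed_corr"], d["weight"]))
            for a, b, d in network.graph.edges(data=True)
        )
        for a, b, corr, w in rows:
            fh.write(f"{a}\t{b}\t{corr:.12g}\t{w:.12g}\n")


def read_weighted_network(path: str | Path):
    """Read a 4-column weighted network TSV (geneA, geneB, signed_corr, weight)."""
    from .coexpression import WeightedNetwork
    import networkx as nx

    path = Path(path)
    if not path.is_file():
        raise InputError(f"weighted network file not found: {path}")
    G = nx.Graph()
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["geneA", "geneB"]:
            raise InputError(f"{path}: unexpected network header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise InputError(f"{path}: line {lineno}: expected 4 columns")
            a, b, corr, w = parts[0], parts[1], float(parts[2]), float(parts[3])
            if a == b:
                raise InputError(f"{path}: line {lineno}: self-edge {a!r}")
            G.add_edge(a, b, signed_corr=corr, weight=w)
    return WeightedNetwork(graph=G, weight_mode="abs_pearson")
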