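"""Data containers and TSV readers/writers for expression matrices and gene networks.

Two primary containers are defined here: :class:`ExpressionMatrix` (genes x
samples, real-valued) and :class:`GeneNetwork` (directed gene-interaction
graph, where an edge j -> i means gene j regulates the expression of gene i).
Loaders accept plain tab-separated text; the expression format carries sample
IDs in a header row and gene IDs in the first column, the network format is a
two-column edge list with optional ``#`` comments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneNetwork",
    "load_expression",
    "write_expression",
    "load_network",
    "write_network",
    "intersect_expression_network",
]


@dataclass
class ExpressionMatrix:
    """A d x n matrix of real expression values with gene and sample IDs.

    Values may be negative (e.g. log-ratios); missing values are not allowed.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        d, n = self.values.shape
        if len(self.gene_ids) != d or len(self.sample_ids) != n:
            raise ValueError(
                f"ID lengths ({len(self.gene_ids)} genes, {len(self.sample_ids)} "
                f"samples) do not match value shape {self.values.shape}"
            )
        if d < 2 or n < 2:
            raise ValueError(f"need at least 2 genes and 2 samples, got {d} x {n}")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene '{self.gene_ids[bad[0]]}', "
                f"sample '{self.sample_ids[bad[1]]}'"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Restrict to ``gene_ids`` (in the given order)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids), self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneNetwork:
    """Directed gene-interaction network on an ordered gene universe.

    ``adjacency`` is an N x N sparse 0/1 matrix with entry (j, i) = 1 iff gene
    j regulates gene i; the in-degree of gene i (number of distinct regulators)
    is therefore the i-th column sum.
    """

    gene_ids: list[str]
    adjacency: sparse.csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        _check_unique(self.gene_ids, "gene")
        n = len(self.gene_ids)
        adj = sparse.csr_matrix(self.adjacency, shape=(n, n), dtype=float)
        if adj.diagonal().any():
            raise ValueError("network adjacency contains self-loops")
        adj.data[:] = 1.0  # collapse any duplicate entries to 0/1
        self.adjacency = adj

    @classmethod
    def from_edges(
        cls, gene_ids: list[str], edges: "set[tuple[int, int]] | list[tuple[int, int]]"
    ) -> "GeneNetwork":
        n = len(gene_ids)
        edges = sorted(set(edges))
        if edges:
            src, dst = zip(*edges)
            adj = sparse.csr_matrix(
                (np.ones(len(edges)), (src, dst)), shape=(n, n), dtype=float
            )
        else:
            adj = sparse.csr_matrix((n, n), dtype=float)
        return cls(list(gene_ids), adj)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz)

    @property
    def edges(self) -> set[tuple[int, int]]:
        """Edge set as (regulator_index, target_index) pairs."""
        src, dst = self.adjacency.nonzero()
        return set(zip(src.tolist(), dst.tolist()))

    @property
    def in_degree(self) -> np.ndarray:
        """Number of distinct regulators per gene (column sums)."""
        return np.asarray(self.adjacency.sum(axis=0)).ravel()

    @property
    def out_degree(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def subset_genes(self, gene_ids: list[str]) -> "GeneNetwork":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        adj = self.adjacency[rows, :][:, rows]
        return GeneNetwork(list(gene_ids), adj)


def _check_unique(ids: list[str], kind: str) -> None:
    seen: set[str] = set()
    for name in ids:
        if name in seen:
            raise ValueError(f"duplicate {kind} ID: '{name}'")
        seen.add(name)


def load_expression(path: str) -> ExpressionMatrix:
    """Read a genes x samples expression TSV.

    The header row holds sample IDs, the first column gene IDs, and the body
    must be fully numeric; row and column order are preserved.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.empty or frame.shape[1] == 0:
        raise ValueError(f"empty expression matrix in {path}")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        try:
            values[:, j] = pd.to_numeric(frame[col], errors="raise")
        except (ValueError, TypeError):
            bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()][0]
            raise ValueError(
                f"non-numeric expression value at gene '{bad}', sample '{col}' in {path}"
            ) from None
    return ExpressionMatrix(list(frame.index), list(frame.columns), values)


def write_expression(expr: ExpressionMatrix, path: str, float_format: str = "%.10g") -> None:
    expr.to_frame().to_csv(path, sep="\t", float_format=float_format)


def load_network(path: str, gene_universe: "list[str] | None" = None) -> GeneNetwork:
    """Read a directed edge list TSV (regulator TAB target).

    Lines starting with ``#`` are comments; a third column, if present, is
    ignored with a warning. Duplicate edges are collapsed, self-loops dropped,
    and — when ``gene_universe`` is given — edges touching genes outside the
    universe are discarded; all three events are counted in the log. With a
    universe the returned network is defined on exactly that gene order.
    """
    pairs: list[tuple[str, str]] = []
    extra_cols = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}")
            if len(fields) > 2:
                extra_cols += 1
            pairs.append((fields[0].strip(), fields[1].strip()))
    if extra_cols:
        warnings.warn(
            f"{path}: ignored extra columns on {extra_cols} line(s); "
            "only (regulator, target) are read",
            stacklevel=2,
        )

    self_loops = sum(1 for a, b in pairs if a == b)
    pairs = [(a, b) for a, b in pairs if a != b]
    if self_loops:
        logger.info("%s: dropped %d self-loop(s)", path, self_loops)

    if gene_universe is not None:
        universe = {g: i for i, g in enumerate(gene_universe)}
        kept = [(a, b) for a, b in pairs if a in universe and b in universe]
        if len(kept) < len(pairs):
            logger.info(
                "%s: discarded %d edge(s) touching genes outside the %d-gene universe",
                path, len(pairs) - len(kept), len(universe),
            )
        gene_ids = list(gene_universe)
        edges = {(universe[a], universe[b]) for a, b in kept}
    else:
        gene_ids = []
        index: dict[str, int] = {}
        for a, b in pairs:
            for g in (a, b):
                if g not in index:
                    index[g] = len(gene_ids)
                    gene_ids.append(g)
        edges = {(index[a], index[b]) for a, b in pairs}

    n_dup = len(pairs) - len(edges)
    if gene_universe is None and n_dup:
        logger.info("%s: collapsed %d duplicate edge(s)", path, n_dup)
    return GeneNetwork.from_edges(gene_ids, edges)


def write_network(net: GeneNetwork, path: str) -> None:
    with open(path, "w") as handle:
        handle.write("# regulator\ttarget\n")
        for src, dst in sorted(net.edges):
            handle.write(f"{net.gene_ids[src]}\t{net.gene_ids[dst]}\n")


def intersect_expression_network(
    expr: ExpressionMatrix, net: GeneNetwork
) -> tuple[ExpressionMatrix, GeneNetwork]:
    """Restrict both inputs to their common genes, in expression-file order.

    Genes absent from either resource are ignored; edges touching removed
    genes are dropped with the genes. Raises if the gene sets are disjoint.
    """
    net_genes = set(net.gene_ids)
    shared = [g for g in expr.gene_ids if g in net_genes]
    if not shared:
        raise ValueError("expression matrix and network share no genes")
    if len(shared) == expr.n_genes and shared == net.gene_ids:
        return expr, net
    logger.info(
        "restricting to %d genes shared by expression (%d) and network (%d)",
        len(shared), expr.n_genes, net.n_genes,
    )
    return expr.subset_genes(shared), net.subset_genes(shared)
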