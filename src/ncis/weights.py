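"""Network-propagated gene weights.

Each gene receives a nonnegative weight reflecting (i) how variable its
expression is across samples, measured by the median absolute deviation (MAD)
normalized to [0, 1] (NMAD), and (ii) how influential it is in a directed
gene-interaction network. The two are combined by a modified PageRank fixed
point in which a regulator inherits weight from its targets:

    w_j = (1 - alpha) * NMAD_j + alpha * sum_i E_ji * w_i / deg_i

where E_ji = 1 iff gene j regulates gene i and deg_i is the number of
regulators of gene i. In matrix form the solution is

    w = (1 - alpha) * (I - alpha * E D^-1)^-1 * NMAD,

with D = diag(deg) and the convention (D^-1)_ii = 0 when deg_i = 0 (a gene
with no regulators contributes nothing to anyone's weight, so the closed form
stays well defined). For 0 <= alpha < 1 the system matrix is nonsingular:
E D^-1 has column sums in {0, 1}, so alpha * E D^-1 is a contraction in the
induced 1-norm. Weights are max-normalized to 1 after solving so that runs
with different alpha are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .io import ExpressionMatrix, GeneNetwork

DEFAULT_ALPHA = 0.85

__all__ = [
    "GeneWeights",
    "compute_mad",
    "compute_nmad",
    "train_weights_closed_form",
    "train_weights_iterative",
    "weights_from_expression",
    "DEFAULT_ALPHA",
]


@dataclass
class GeneWeights:
    """Per-gene nonnegative weights, max-normalized to 1."""

    gene_ids: list[str]
    w: np.ndarray
    alpha: float
    nmad: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.nmad = np.asarray(self.nmad, dtype=float)
        if (self.w < 0).any():
            raise ValueError("gene weights must be nonnegative")

    def as_diagonal(self) -> np.ndarray:
        """The diagonal weight matrix W consumed by the co-clustering objective."""
        return np.diag(self.w)


def compute_mad(expr: ExpressionMatrix) -> np.ndarray:
    """Median absolute deviation of each gene's expression across samples."""
    x = expr.values
    med = np.median(x, axis=1, keepdims=True)
    return np.median(np.abs(x - med), axis=1)


def compute_nmad(mad: np.ndarray) -> np.ndarray:
    """Normalize MAD values by their maximum, mapping them into [0, 1].

    An all-zero input (every gene constant across samples) yields all zeros
    with a warning instead of dividing by zero.
    """
    mad = np.asarray(mad, dtype=float)
    if (mad < 0).any():
        raise ValueError("MAD values must be nonnegative")
    top = mad.max(initial=0.0)
    if top == 0.0:
        warnings.warn("all MAD values are zero; NMAD set to zero for every gene", stacklevel=2)
        return np.zeros_like(mad)
    return mad / top


def _propagation_matrix(net: GeneNetwork) -> sparse.csr_matrix:
    """E D^-1 with zero columns where a gene has no regulators."""
    deg = net.in_degree
    inv = np.zeros_like(deg)
    nz = deg > 0
    inv[nz] = 1.0 / deg[nz]
    return net.adjacency @ sparse.diags(inv)


def _check_inputs(net: GeneNetwork, nmad: np.ndarray, alpha: float) -> np.ndarray:
    nmad = np.asarray(nmad, dtype=float)
    if nmad.shape != (net.n_genes,):
        raise ValueError(
            f"NMAD length {nmad.shape} does not match the {net.n_genes}-gene network"
        )
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must lie in [0, 1), got {alpha}")
    return nmad


def _finalize(net: GeneNetwork, w: np.ndarray, nmad: np.ndarray, alpha: float,
              normalize: bool) -> GeneWeights:
    w = np.maximum(w, 0.0)  # clip solver round-off; the true solution is nonnegative
    top = w.max(initial=0.0)
    if top == 0.0:
        raise ValueError(
            "all gene weights are zero (no gene varies across samples); "
            "weighted co-clustering would be degenerate"
        )
    if normalize:
        w = w / top
    return GeneWeights(list(net.gene_ids), w, alpha, nmad)


def train_weights_closed_form(
    net: GeneNetwork,
    nmad: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = True,
) -> GeneWeights:
    """Solve the weight fixed point directly: (I - alpha E D^-1) w = (1-alpha) NMAD."""
    nmad = _check_inputs(net, nmad, alpha)
    if alpha == 0.0:
        w = nmad.copy()
    else:
        n = net.n_genes
        system = sparse.identity(n, format="csc") - alpha * _propagation_matrix(net).tocsc()
        w = spsolve(system, (1.0 - alpha) * nmad)
    return _finalize(net, np.atleast_1d(w), nmad, alpha, normalize)


def train_weights_iterative(
    net: GeneNetwork,
    nmad: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    tol: float = 1e-10,
    max_iter: int = 1000,
    normalize: bool = True,
) -> GeneWeights:
    """Solve the weight fixed point by damped iteration from w0 = NMAD.

    Each sweep contracts the max-norm error by at least a factor alpha, so the
    result agrees with :func:`train_weights_closed_form` to roughly ``tol``.
    Raises if the residual has not dropped below ``tol`` after ``max_iter``
    sweeps.
    """
    nmad = _check_inputs(net, nmad, alpha)
    prop = _propagation_matrix(net).tocsr()
    w = nmad.copy()
    seed = (1.0 - alpha) * nmad
    for _ in range(max_iter):
        w_new = seed + alpha * (prop @ w)
        residual = np.max(np.abs(w_new - w), initial=0.0)
        w = w_new
        if residual < tol:
            return _finalize(net, w, nmad, alpha, normalize)
    raise RuntimeError(
        f"weight iteration did not converge in {max_iter} sweeps "
        f"(last max-norm change {residual:.3e} >= tol {tol:.3e})"
    )


def weights_from_expression(
    expr: ExpressionMatrix,
    net: GeneNetwork,
    alpha: float = DEFAULT_ALPHA,
    method: str = "closed",
    **kwargs,
) -> GeneWeights:
    """Full weighting pipeline: MAD -> NMAD -> network propagation.

    ``expr`` and ``net`` must already share the same gene order (see
    :func:`ncis.io.intersect_expression_network`).
    """
    if expr.gene_ids != net.gene_ids:
        raise ValueError("expression and network gene orders differ; intersect them first")
    nmad = compute_nmad(compute_mad(expr))
    if method == "closed":
        return train_weights_closed_form(net, nmad, alpha, **kwargs)
    if method == "iterative":
        return train_weights_iterative(net, nmad, alpha, **kwargs)
    raise ValueError(f"unknown method '{method}' (expected 'closed' or 'iterative')")
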