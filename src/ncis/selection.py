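"""Cluster-number selection by consensus stability over random initializations.

The co-clustering optimizer converges to different local minima from different
random starts; if the clustering structure is strong the hard assignments are
nevertheless stable. Stability is quantified by running the fit ``n_runs``
times, averaging the 0/1 same-cluster connectivity matrices into consensus
matrices for samples and genes, and scoring each consensus matrix by its
cophenetic correlation coefficient rho — the Pearson correlation between the
consensus-induced distances (1 - consensus) and the ultrametric distances of
an average-linkage dendrogram built from them. A perfectly reproducible
clustering yields a 0/1 consensus matrix and rho = 1 exactly. Candidate
(m, c) pairs are compared by the average of the sample and gene coefficients,
and the suggested pair is where the averaged coefficient is still high just
before it starts to decrease with growing c.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from . import cocluster

DEFAULT_N_RUNS = 50

__all__ = [
    "ConsensusResult",
    "connectivity_matrix",
    "consensus",
    "consensus_labels",
    "cophenetic_coefficient",
    "select_m_c",
    "DEFAULT_N_RUNS",
]


@dataclass
class ConsensusResult:
    """Averaged connectivity matrices and their cophenetic coefficients."""

    consensus_samples: np.ndarray
    consensus_genes: np.ndarray
    rho_samples: float
    rho_genes: float
    n_runs: int
    m: int
    c: int
    sample_labels_per_run: np.ndarray  # n_runs x n
    gene_labels_per_run: np.ndarray  # n_runs x d

    @property
    def rho_average(self) -> float:
        return (self.rho_samples + self.rho_genes) / 2.0


def connectivity_matrix(labels) -> np.ndarray:
    """0/1 symmetric matrix with entry (i, j) = 1 iff items i and j share a cluster."""
    labels = np.asarray(labels).ravel()
    if labels.size < 1:
        raise ValueError("labels must be non-empty")
    return (labels[:, None] == labels[None, :]).astype(float)


def cophenetic_coefficient(consensus: np.ndarray, linkage_method: str = "average") -> float:
    """Cophenetic correlation of a consensus matrix under average-linkage clustering.

    Builds distances 1 - consensus, clusters them hierarchically, and returns
    the Pearson correlation between the condensed input distances and the
    dendrogram's cophenetic distances. A constant distance vector (perfectly
    stable consensus) is scored 1 with a warning, since the correlation is
    undefined but the clustering could not be more reproducible.
    """
    consensus = np.asarray(consensus, dtype=float)
    if consensus.ndim != 2 or consensus.shape[0] != consensus.shape[1]:
        raise ValueError("consensus must be a square matrix")
    if not np.allclose(consensus, consensus.T, atol=1e-12):
        raise ValueError("consensus matrix must be symmetric")
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if condensed.size == 0 or np.ptp(condensed) == 0.0:
        warnings.warn("constant consensus distances; cophenetic coefficient set to 1",
                      stacklevel=2)
        return 1.0
    Z = hierarchy.linkage(condensed, method=linkage_method)
    coph = hierarchy.cophenet(Z)
    if np.ptp(coph) == 0.0:
        warnings.warn("constant cophenetic distances; coefficient set to 1", stacklevel=2)
        return 1.0
    if np.array_equal(condensed, coph):
        # the dendrogram reproduces the distances exactly (e.g. a 0/1
        # partition-consistent consensus); the correlation is exactly 1
        return 1.0
    return float(np.clip(pearsonr(condensed, coph).statistic, -1.0, 1.0))


def consensus_labels(consensus_matrix: np.ndarray, k: int,
                     linkage_method: str = "average") -> np.ndarray:
    """Hard labels from a consensus matrix: cluster the distances 1 - consensus.

    Average-linkage hierarchical clustering cut into ``k`` groups. Because the
    consensus matrix pools many random-start fits, these labels are far more
    stable than any single run's argmax assignment and are the recommended
    final partition.
    """
    consensus_matrix = np.asarray(consensus_matrix, dtype=float)
    dist = 1.0 - consensus_matrix
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    return hierarchy.fcluster(Z, k, criterion="maxclust")


def consensus(
    X: np.ndarray,
    w,
    m: int,
    c: int,
    n_runs: int = DEFAULT_N_RUNS,
    base_seed: int = 0,
    **fit_kwargs,
) -> ConsensusResult:
    """Average same-cluster connectivity over ``n_runs`` random-start fits.

    Run r uses seed ``base_seed + r``, so the whole procedure is reproducible
    from one integer. Each run is a single random start (``n_init=1`` unless
    overridden): the ensemble itself provides the restarts. Fit failures abort
    with the failing seed reported.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be at least 2")
    X = np.asarray(X, dtype=float)
    d, n = X.shape
    sample_sum = np.zeros((n, n))
    gene_sum = np.zeros((d, d))
    sample_labels = np.empty((n_runs, n), dtype=int)
    gene_labels_all = np.empty((n_runs, d), dtype=int)
    fit_kwargs.setdefault("n_init", 1)
    for r in range(n_runs):
        seed = int(base_seed) + r
        try:
            model = cocluster.fit(X, w, m, c, seed=seed, **fit_kwargs)
        except Exception as err:
            raise RuntimeError(f"consensus run with seed {seed} failed: {err}") from err
        sample_labels[r] = model.sample_labels
        gene_labels_all[r] = model.gene_labels
        sample_sum += connectivity_matrix(sample_labels[r])
        gene_sum += connectivity_matrix(gene_labels_all[r])
    consensus_samples = sample_sum / n_runs
    consensus_genes = gene_sum / n_runs
    return ConsensusResult(
        consensus_samples=consensus_samples,
        consensus_genes=consensus_genes,
        rho_samples=cophenetic_coefficient(consensus_samples),
        rho_genes=cophenetic_coefficient(consensus_genes),
        n_runs=n_runs,
        m=m,
        c=c,
        sample_labels_per_run=sample_labels,
        gene_labels_per_run=gene_labels_all,
    )


def _per_m_candidate(sub: pd.DataFrame):
    """Last c before the first strict decrease of rho_average (max c if non-decreasing)."""
    sub = sub.sort_values("c")
    rho = sub["rho_average"].to_numpy()
    idx = len(rho) - 1
    hit_boundary = True
    for i in range(1, len(rho)):
        if rho[i] < rho[i - 1]:
            idx = i - 1
            hit_boundary = False
            break
    return sub.iloc[idx], hit_boundary


def select_m_c(
    X: np.ndarray,
    w,
    grid: "list[tuple[int, int]]",
    n_runs: int = DEFAULT_N_RUNS,
    base_seed: int = 0,
    **fit_kwargs,
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Evaluate consensus stability on a grid of (m, c) and suggest a pair.

    Returns the full coefficient table (columns m, c, rho_samples, rho_genes,
    rho_average) and the suggestion: for each m the last c before rho_average
    first strictly decreases (the largest c when it never does, with a warning
    to extend the grid), then the candidate with the highest rho_average, ties
    broken by smaller c then smaller m. The table is always returned in full so
    the heuristic can be overridden.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    rows = []
    for m, c in grid:
        res = consensus(X, w, m, c, n_runs=n_runs, base_seed=base_seed, **fit_kwargs)
        rows.append(dict(m=m, c=c, rho_samples=res.rho_samples,
                         rho_genes=res.rho_genes, rho_average=res.rho_average))
    table = pd.DataFrame(rows)

    candidates = []
    any_boundary = False
    for m, sub in table.groupby("m"):
        cand, boundary = _per_m_candidate(sub)
        any_boundary = any_boundary or (boundary and len(sub) > 1)
        candidates.append(cand)
    if any_boundary:
        warnings.warn(
            "rho_average never decreased along c for at least one m; "
            "consider extending the grid to larger c",
            stacklevel=2,
        )
    cand = pd.DataFrame(candidates).sort_values(
        by=["rho_average", "c", "m"], ascending=[False, True, True]
    ).iloc[0]
    return table, (int(cand["m"]), int(cand["c"]))
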