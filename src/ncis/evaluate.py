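"""Scoring clusterings against ground truth and ranking subtype-discriminating genes."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .io import ExpressionMatrix

__all__ = [
    "EvaluationReport",
    "clustering_accuracy",
    "anova_per_gene",
    "top_shared_genes",
]


@dataclass
class EvaluationReport:
    """Bundle of clustering-vs-truth and per-gene discrimination results."""

    accuracy: float
    matched_label_map: dict
    per_gene_pvalues: "np.ndarray | None" = None
    top_shared_genes: "list | None" = None


def _match_labels(pred: np.ndarray, truth: np.ndarray):
    """Optimal one-to-one mapping of predicted to true labels on the contingency table."""
    pred_vals, pred_idx = np.unique(pred, return_inverse=True)
    true_vals, true_idx = np.unique(truth, return_inverse=True)
    table = np.zeros((pred_vals.size, true_vals.size), dtype=int)
    np.add.at(table, (pred_idx, true_idx), 1)
    rows, cols = linear_sum_assignment(table, maximize=True)
    mapping = {pred_vals[r]: true_vals[c] for r, c in zip(rows, cols)}
    return table, rows, cols, mapping


def clustering_accuracy(pred, truth) -> float:
    """Fraction of samples assigned correctly under the best label permutation.

    Label matching solves the optimal assignment on the contingency table, so
    the value is invariant to any relabeling of either input; when the two
    clusterings have different numbers of clusters, unmatched clusters
    contribute no correct samples.
    """
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError(f"label vectors differ in length: {pred.size} vs {truth.size}")
    table, rows, cols, _ = _match_labels(pred, truth)
    return float(table[rows, cols].sum() / pred.size)


def matched_label_map(pred, truth) -> dict:
    """The optimal predicted-to-true label mapping used by :func:`clustering_accuracy`."""
    return _match_labels(np.asarray(pred).ravel(), np.asarray(truth).ravel())[3]


def anova_per_gene(expr: ExpressionMatrix, labels) -> np.ndarray:
    """One-way fixed-effects ANOVA p-value per gene across sample clusters.

    Requires at least 2 clusters, each with at least 2 samples. A gene that is
    constant within clusters but differs between them has F -> infinity; its
    p-value is reported as the smallest positive float. A gene constant across
    all samples carries no information and gets p = 1.
    """
    labels = np.asarray(labels).ravel()
    if labels.size != expr.n_samples:
        raise ValueError("label vector length does not match the number of samples")
    values, counts = np.unique(labels, return_counts=True)
    if values.size < 2:
        raise ValueError("need at least 2 clusters for ANOVA")
    if (counts < 2).any():
        small = values[counts < 2]
        raise ValueError(f"cluster(s) {small.tolist()} have fewer than 2 samples")
    groups = [expr.values[:, labels == v] for v in values]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant rows raise ConstantInputWarning
        result = stats.f_oneway(*groups, axis=1)
    pvals = np.asarray(result.pvalue, dtype=float)
    fstat = np.asarray(result.statistic, dtype=float)
    pvals[np.isinf(fstat)] = np.finfo(float).tiny
    pvals[np.isnan(pvals)] = 1.0  # constant across all samples
    return np.clip(pvals, np.finfo(float).tiny, 1.0)


def top_shared_genes(gene_ids, pvalues, weights, k: int) -> list:
    """First ``k`` genes shared between the p-value and gene-weight rankings.

    Both rankings are walked in lockstep prefixes (p-values ascending, weights
    descending, ties broken by gene order): at prefix length t the genes
    present in both length-t prefixes are collected, and the walk stops once
    ``k`` genes have been found. The result is ordered by p-value ascending
    and truncated to ``k``. Asking for more genes than exist returns all
    shared genes with a warning.
    """
    gene_ids = list(gene_ids)
    pvalues = np.asarray(pvalues, dtype=float)
    weights = np.asarray(weights, dtype=float)
    d = len(gene_ids)
    if pvalues.shape != (d,) or weights.shape != (d,):
        raise ValueError("gene_ids, pvalues and weights must be aligned")
    if k > d:
        warnings.warn(f"k={k} exceeds the {d}-gene universe; returning all shared genes",
                      stacklevel=2)
    p_order = np.argsort(pvalues, kind="stable")
    w_order = np.argsort(-weights, kind="stable")

    in_p: set[int] = set()
    in_w: set[int] = set()
    shared: list[int] = []
    for t in range(d):
        step_new = []
        gp, gw = int(p_order[t]), int(w_order[t])
        in_p.add(gp)
        in_w.add(gw)
        if gp in in_w:
            step_new.append(gp)
        if gw != gp and gw in in_p:
            step_new.append(gw)
        shared.extend(step_new)
        if len(shared) >= k:
            break
    shared.sort(key=lambda i: (pvalues[i], i))
    return [gene_ids[i] for i in shared[:k]]
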