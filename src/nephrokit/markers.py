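"""Cluster marker detection and reference-based cell-type assignment.

Markers are detected per cluster by comparing each cluster's cells against
all other cells of the same organoid: a gene is tested only if its
de-logged mean fold change passes the cutoff (1.8-fold, either direction),
p-values come from a two-sided Wilcoxon rank-sum test (exact enumeration for
small groups, tie-corrected normal approximation otherwise), and Bonferroni
correction uses the total number of genes in the matrix — the denominator
the single-cell ecosystem's marker functions use, and the one that keeps the
procedure calibrated despite the fold pre-filter selecting noise-extreme
genes (the number actually tested is recorded per comparison so the
alternative denominator is auditable).

Cell typing correlates each cell's expression profile with every column of a
labeled reference matrix (Spearman over shared genes); each cell takes the
best-correlated label and each cluster the modal label of its cells, ties
broken alphabetically.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError

#: both group sizes at or below this use exact rank-sum enumeration
EXACT_MAX_N = 8

FOLD_EPS = 1e-9


def rank_sum_p_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p-value by enumerating all group assignments.

    Mid-ranks are used, so ties are handled exactly. The two-sided p-value is
    ``min(1, 2 * min(P(W <= w), P(W >= w)))`` over the permutation
    distribution of the first group's rank sum W.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    ranks = scipy.stats.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n1].sum()
    total = math.comb(n1 + n2, n1)
    le = ge = 0
    for idx in combinations(range(n1 + n2), n1):
        w = ranks[list(idx)].sum()
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def _rank_sum_p_asymptotic(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p, tie-corrected normal approximation."""
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Dispatch: exact enumeration when both groups are small, else asymptotic."""
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        return rank_sum_p_exact(x, y)
    return _rank_sum_p_asymptotic(x, y)


def bonferroni(p: np.ndarray | float, m: int) -> np.ndarray | float:
    """Bonferroni adjustment ``min(1, m * p)``."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    adj = np.minimum(1.0, m * p_arr)
    return float(adj) if np.isscalar(p) or p_arr.ndim == 0 else adj


def wilcoxon_markers(
    norm: pd.DataFrame,
    labels: pd.DataFrame,
    fold_cutoff: float = 1.8,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cluster marker table.

    *norm* is the log-normalized genes x cells matrix; *labels* has columns
    ``cell``, ``cluster``, ``organoid``. For every organoid and every cluster
    within it (>= 2 cells on both sides, else skipped with a warning), fold
    change is computed on de-logged means with pseudocount ``1e-9``; genes
    with fold >= *fold_cutoff* or <= 1/*fold_cutoff* are tested. Bonferroni
    uses m = number of genes in the matrix. Returns columns ``organoid,
    cluster, gene, fold_change, direction, p_value, n_tested, p_bonferroni,
    significant``.
    """
    if fold_cutoff <= 1:
        raise ValidationError("fold_cutoff must be > 1")
    labels = labels.set_index("cell") if "cell" in labels.columns else labels
    missing = [c for c in norm.columns if c not in labels.index]
    if missing:
        raise ValidationError(f"cells without labels: {missing[:5]}")
    expr = np.expm1(norm.to_numpy(dtype=float))
    cells = list(norm.columns)
    organoids = labels.loc[cells, "organoid"].to_numpy()
    clusters = labels.loc[cells, "cluster"].to_numpy()

    rows = []
    for org in pd.unique(organoids):
        org_mask = organoids == org
        for clust in pd.unique(clusters[org_mask]):
            in_mask = org_mask & (clusters == clust)
            out_mask = org_mask & (clusters != clust)
            if in_mask.sum() < 2 or out_mask.sum() < 2:
                warnings.warn(
                    f"cluster {clust!r} in organoid {org!r} skipped: fewer than 2 cells on one side",
                    stacklevel=2,
                )
                continue
            mean_in = expr[:, in_mask].mean(axis=1)
            mean_out = expr[:, out_mask].mean(axis=1)
            fold = (mean_in + FOLD_EPS) / (mean_out + FOLD_EPS)
            tested = (fold >= fold_cutoff) | (fold <= 1.0 / fold_cutoff)
            m = int(tested.sum())
            if m == 0:
                continue
            x_in = norm.to_numpy()[:, in_mask]
            x_out = norm.to_numpy()[:, out_mask]
            small = in_mask.sum() <= EXACT_MAX_N and out_mask.sum() <= EXACT_MAX_N
            tested_idx = np.flatnonzero(tested)
            if small:
                pvals = np.array([rank_sum_p_exact(x_in[i], x_out[i]) for i in tested_idx])
            else:
                with np.errstate(invalid="ignore"):
                    res = scipy.stats.mannwhitneyu(
                        x_in[tested_idx], x_out[tested_idx], alternative="two-sided", method="asymptotic", axis=1
                    )
                pvals = np.nan_to_num(np.asarray(res.pvalue, dtype=float), nan=1.0)
            p_adj = np.minimum(1.0, norm.shape[0] * pvals)
            for i, p, padj in zip(tested_idx, pvals, p_adj):
                rows.append(
                    {
                        "organoid": org,
                        "cluster": clust,
                        "gene": norm.index[i],
                        "fold_change": fold[i],
                        "direction": "up" if fold[i] >= fold_cutoff else "down",
                        "p_value": p,
                        "n_tested": m,
                        "p_bonferroni": padj,
                        "significant": bool(padj < alpha),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "organoid",
            "cluster",
            "gene",
            "fold_change",
            "direction",
            "p_value",
            "n_tested",
            "p_bonferroni",
            "significant",
        ],
    )


def assign_cell_types(
    norm: pd.DataFrame,
    labels: pd.DataFrame,
    reference: pd.DataFrame,
    min_shared_genes: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference-based cell typing by Spearman correlation and majority vote.

    *reference* is genes x cell-types. Each cell is assigned the
    best-correlated reference label (Spearman over the shared genes;
    deterministic alphabetical tie-break); each cluster the modal label of
    its cells, ties again alphabetical. Returns (per-cell, per-cluster)
    tables.
    """
    shared = norm.index.intersection(reference.index)
    if len(shared) < min_shared_genes:
        raise ValidationError(
            f"only {len(shared)} genes shared with the reference (need >= {min_shared_genes})"
        )
    ref_cols = sorted(reference.columns)
    x = norm.loc[shared].to_numpy(dtype=float)
    r = reference.loc[shared, ref_cols].to_numpy(dtype=float)
    # Spearman = Pearson on mid-ranks, computed column-wise
    xr = scipy.stats.rankdata(x, axis=0)
    rr = scipy.stats.rankdata(r, axis=0)
    xr = xr - xr.mean(axis=0, keepdims=True)
    rr = rr - rr.mean(axis=0, keepdims=True)
    xn = np.linalg.norm(xr, axis=0)
    rn = np.linalg.norm(rr, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xr.T @ rr) / np.outer(np.where(xn == 0, np.nan, xn), np.where(rn == 0, np.nan, rn))
    corr = np.nan_to_num(corr, nan=-np.inf)
    best = corr.argmax(axis=1)  # argmax takes the first (alphabetically smallest) on ties
    per_cell = pd.DataFrame(
        {
            "cell": list(norm.columns),
            "cell_type": [ref_cols[i] for i in best],
            "correlation": corr[np.arange(len(best)), best],
        }
    )
    lab = labels.set_index("cell") if "cell" in labels.columns else labels
    per_cell["cluster"] = lab.loc[per_cell["cell"], "cluster"].to_numpy()
    votes = []
    for clust, group in per_cell.groupby("cluster", sort=True):
        counts = group["cell_type"].value_counts()
        top = counts.max()
        winner = sorted(counts.index[counts == top])[0]
        votes.append({"cluster": clust, "cell_type": winner, "n_cells": len(group)})
    return per_cell, pd.DataFrame(votes)
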