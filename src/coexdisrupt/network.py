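"""Weighted coexpression network construction and module detection.

The network is *unsigned*: the connection strength between transcripts i and
j is ``a_ij = |cor(x_i, x_j)| ** beta`` with a soft-threshold exponent beta
(default 10), so both positively and negatively correlated transcripts are
connected.  Modules are branches of an average-linkage dendrogram of the
dissimilarity ``1 - a_ij`` (optionally of a topological-overlap
dissimilarity), cut at the highest height yielding at least two sufficiently
large clusters, then iteratively merged when their eigengenes are highly
correlated.  Module membership is validated against random same-size
transcript sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import (
    GREY,
    AdjacencyNetwork,
    DegenerateInputError,
    ExpressionMatrix,
    ModulePartition,
)
from .synthetic import MODULE_COLORS

logger = logging.getLogger(__name__)


def build_adjacency(expr: ExpressionMatrix, beta: float = 10.0) -> AdjacencyNetwork:
    """Unsigned soft-threshold adjacency ``|Pearson cor| ** beta``.

    Constant transcripts (undefined correlation) get weight 0 to all
    partners, with a logged count.  Diagonal is 0 by convention so that
    connectivity sums run over distinct partners.
    """
    if expr.n_samples < 3:
        raise ValueError("adjacency needs >= 3 samples")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    x = expr.values.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.info("%d constant transcripts set to zero adjacency", constant.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr[np.isnan(corr)] = 0.0
    weights = np.abs(np.clip(corr, -1.0, 1.0)) ** beta
    weights[constant, :] = 0.0
    weights[:, constant] = 0.0
    np.fill_diagonal(weights, 0.0)
    return AdjacencyNetwork(weights, expr.transcript_ids, beta)


def scale_free_fit(adj: AdjacencyNetwork, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log connectivity histogram regression.

    Bins whole-network connectivity, regresses log10(frequency) on
    log10(mean bin connectivity) and returns R^2 with the sign of the
    *negative* slope (a decreasing power law gives a positive value).
    Diagnostic only — beta stays user-set.
    """
    k = adj.connectivity()
    if np.allclose(k, k[0]):
        raise DegenerateInputError("all connectivities equal: single bin")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_f = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        log_k.append(np.log10(mean_k))
        log_f.append(np.log10(mask.sum() / len(k)))
    if len(log_k) < 2:
        raise DegenerateInputError("fewer than 2 occupied connectivity bins")
    slope, intercept = np.polyfit(log_k, log_f, 1)
    fitted = slope * np.asarray(log_k) + intercept
    resid = np.asarray(log_f) - fitted
    ss_tot = np.sum((np.asarray(log_f) - np.mean(log_f)) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
    return float(r2 if slope < 0 else -r2)


def consensus_adjacency(networks: list[AdjacencyNetwork]) -> AdjacencyNetwork:
    """Element-wise mean adjacency across datasets on a common node set."""
    if len(networks) < 2:
        raise ValueError("consensus needs >= 2 networks")
    first = networks[0]
    for net in networks[1:]:
        if not net.transcript_ids.equals(first.transcript_ids):
            raise ValueError("networks must share transcript ids and order")
        if net.beta != first.beta:
            raise ValueError("networks must share beta")
    mean = np.mean([net.weights for net in networks], axis=0)
    return AdjacencyNetwork(mean, first.transcript_ids, first.beta)


def topological_overlap(adj: AdjacencyNetwork) -> np.ndarray:
    """Topological overlap matrix (classic WGCNA variant, optional)."""
    a = adj.weights
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    return tom


def module_eigengene(expr: ExpressionMatrix, members) -> pd.Series:
    """First principal component of the standardized member profiles.

    Returns the per-sample score vector with unit-norm loadings, sign
    oriented so the mean correlation with member profiles is >= 0.
    """
    members = pd.Index(members)
    if len(members) < 2:
        raise ValueError("eigengene needs >= 2 members")
    x = expr.values.loc[members].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    if (sd == 0).all():
        raise DegenerateInputError("all member profiles constant")
    keep = sd > 0
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    # right singular vector = per-sample scores of the first PC
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_cor = np.mean([np.corrcoef(eig, row)[0, 1] for row in z])
    if mean_cor < 0:
        eig = -eig
    return pd.Series(eig, index=expr.sample_ids, name="eigengene")


def _merge_close_modules(
    expr: ExpressionMatrix, assignment: pd.Series, merge_cut: float
) -> pd.Series:
    """Iteratively merge module pairs whose eigengene correlation
    is >= 1 - merge_cut; the larger module's label wins."""
    assignment = assignment.copy()
    while True:
        labels = sorted(set(assignment) - {GREY})
        if len(labels) < 2:
            return assignment
        eigs = {
            lab: module_eigengene(expr, assignment.index[assignment == lab])
            for lab in labels
        }
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                c = float(np.corrcoef(eigs[a], eigs[b])[0, 1])
                if c >= 1.0 - merge_cut and (best is None or c > best[0]):
                    best = (c, a, b)
        if best is None:
            return assignment
        _, a, b = best
        sizes = assignment.value_counts()
        winner, loser = (a, b) if sizes[a] >= sizes[b] else (b, a)
        assignment[assignment == loser] = winner


def detect_modules(
    adj: AdjacencyNetwork,
    expr: ExpressionMatrix,
    min_module_size: int = 30,
    merge_cut: float = 0.25,
    use_tom: bool = False,
    n_heights: int = 100,
) -> ModulePartition:
    """Dendrogram-based module detection with eigengene merging.

    Average-linkage clustering of ``1 - adjacency`` (or 1 - TOM when
    ``use_tom``); the dendrogram is cut on a height grid at the highest
    height producing >= 2 clusters of size >= ``min_module_size``; branches
    below the size threshold become grey.  Modules with eigengene
    correlation >= ``1 - merge_cut`` are then merged iteratively.
    """
    if min_module_size < 3:
        raise ValueError("min_module_size must be >= 3")
    n = adj.n_nodes
    if n < min_module_size:
        return ModulePartition(pd.Series(GREY, index=adj.transcript_ids))
    sim = topological_overlap(adj) if use_tom else adj.weights.copy()
    np.fill_diagonal(sim, 1.0)
    diss = 1.0 - sim
    diss = (diss + diss.T) / 2.0
    np.fill_diagonal(diss, 0.0)
    link = linkage(squareform(diss, checks=False), method="average")

    heights = np.unique(link[:, 2])
    grid = np.unique(
        np.concatenate([heights, np.linspace(heights.min(), heights.max(), n_heights)])
    )
    best_labels: np.ndarray | None = None
    best_n_big = 1
    for h in grid:  # ascending; prefer most big branches, then highest height
        labels = fcluster(link, t=h, criterion="distance")
        n_big = int((np.bincount(labels) >= min_module_size).sum())
        if n_big >= max(2, best_n_big):
            best_labels = labels
            best_n_big = n_big
    if best_labels is None:
        return ModulePartition(pd.Series(GREY, index=adj.transcript_ids))

    counts = np.bincount(best_labels)
    big = [c for c in np.unique(best_labels) if counts[c] >= min_module_size]
    # deterministic naming: largest module first
    big.sort(key=lambda c: (-counts[c], c))
    name_of = {c: MODULE_COLORS[i % len(MODULE_COLORS)] for i, c in enumerate(big)}
    assignment = pd.Series(
        [name_of.get(c, GREY) for c in best_labels], index=adj.transcript_ids
    )
    assignment = _merge_close_modules(expr, assignment, merge_cut)
    # merging can only grow modules, so the size floor still holds
    return ModulePartition(assignment)


def validate_modules(
    adj: AdjacencyNetwork,
    partition: ModulePartition,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Permutation p-value that each module is denser than random sets.

    For every module, ``p = (1 + #{random same-size sets with mean
    within-set adjacency >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    w = adj.weights
    n = adj.n_nodes
    pos = {t: i for i, t in enumerate(adj.transcript_ids)}
    pvals = {}
    for label in partition.labels:
        idx = np.array([pos[t] for t in partition.members(label)])
        size = len(idx)
        if size > n:
            raise ValueError("module larger than network")
        obs = _mean_within_adjacency(w, idx)
        hits = 0
        for _ in range(n_perm):
            rand = rng.choice(n, size=size, replace=False)
            if _mean_within_adjacency(w, rand) >= obs:
                hits += 1
        pvals[label] = (1 + hits) / (n_perm + 1)
    return pd.Series(pvals, name="p_value")


def _mean_within_adjacency(w: np.ndarray, idx: np.ndarray) -> float:
    sub = w[np.ix_(idx, idx)]
    m = len(idx)
    if m < 2:
        return 0.0
    return float(sub.sum() / (m * (m - 1)))
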