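"""Per-node network statistics and per-module preservation correlations.

Five node statistics summarise how a transcript sits in the network:

- ``kIM``:   intramodular connectivity, the sum of adjacency weights to the
             other members of the node's own module;
- ``kME``:   correlation of the node's profile with its own module eigengene;
- ``kMEall``: the vector of correlations with *every* module eigengene;
- ``clusterCoeff``: weighted clustering coefficient,
             sum_{j!=k} a_ij a_jk a_ki / ((sum_j a_ij)^2 - sum_j a_ij^2);
- ``MAR``:   maximum adjacency ratio, sum_j a_ij^2 / sum_j a_ij — a weighted
             mean of a node's weights, large when connectivity concentrates
             on a few strong edges.

Preservation between two networks built over the same nodes is the Pearson
correlation, per module, of each statistic vector across member nodes
(``cor.kIM`` etc.), plus ``cor.ADJ``, the correlation of the within-module
upper-triangle adjacency entries.  High values mean preserved wiring; the
disruption analysis asks whether they are *lower* than chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    GREY,
    AdjacencyNetwork,
    ExpressionMatrix,
    ModulePartition,
)
from .network import module_eigengene

logger = logging.getLogger(__name__)

PRESERVATION_STATS = [
    "cor.kIM",
    "cor.kME",
    "cor.kMEall",
    "cor.ADJ",
    "cor.clusterCoeff",
    "cor.MAR",
]


@dataclass
class NodeStatsTable:
    """Per-node statistics; ``kme_all`` has one column per module eigengene."""

    stats: pd.DataFrame  # columns: module, kIM, kME, clusterCoeff, MAR
    kme_all: pd.DataFrame  # transcripts x module labels

    def __post_init__(self) -> None:
        if not self.stats.index.equals(self.kme_all.index):
            raise ValueError("stats and kme_all must share the transcript index")


def compute_node_statistics(
    adj: AdjacencyNetwork,
    expr: ExpressionMatrix,
    partition: ModulePartition,
) -> NodeStatsTable:
    """All five node statistics for every transcript.

    Eigengenes are computed from ``expr`` (this network's own samples) over
    the supplied (typically consensus) module memberships.  ``clusterCoeff``
    and ``MAR`` use whole-network adjacency and default to 0 for isolated
    nodes (zero denominator), with a logged count; grey transcripts get kIM
    and kME over the grey set.
    """
    ids = adj.transcript_ids
    if not ids.equals(expr.transcript_ids) or not ids.equals(
        partition.transcript_ids
    ):
        raise ValueError("adjacency, expression and partition must share index")
    w = adj.weights
    x = expr.values.to_numpy(dtype=float)
    k = w.sum(axis=1)
    sq = (w**2).sum(axis=1)

    # clusterCoeff_i = (A^3)_ii / (k_i^2 - sum_j a_ij^2); MAR_i = sq_i / k_i
    triangles = ((w @ w) * w).sum(axis=1)  # (A^3)_ii with zero diagonal
    denom_cc = k**2 - sq
    n_isolated = int(((denom_cc <= 0) | (k <= 0)).sum())
    if n_isolated:
        logger.info("%d isolated nodes: clusterCoeff/MAR set to 0", n_isolated)
    with np.errstate(invalid="ignore", divide="ignore"):
        cluster_coeff = np.where(denom_cc > 0, triangles / denom_cc, 0.0)
        mar = np.where(k > 0, sq / k, 0.0)

    labels = partition.labels
    eigs: dict[str, np.ndarray] = {}
    for lab in labels:
        members = partition.members(lab)
        eigs[lab] = module_eigengene(expr, members).to_numpy()

    def _corr_with(vec: np.ndarray) -> np.ndarray:
        """Correlation of every transcript profile with one sample vector."""
        xc = x - x.mean(axis=1, keepdims=True)
        vc = vec - vec.mean()
        denom = np.sqrt((xc**2).sum(axis=1) * (vc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (xc @ vc) / denom
        return np.where(np.isfinite(out), out, 0.0)

    kme_all = pd.DataFrame(
        {lab: _corr_with(eigs[lab]) for lab in labels}, index=ids
    )

    assignment = partition.assignment
    kim = np.zeros(len(ids))
    kme = np.zeros(len(ids))
    pos = {t: i for i, t in enumerate(ids)}
    for lab in labels + [GREY]:
        members = assignment.index[assignment == lab]
        if len(members) == 0:
            continue
        idx = np.array([pos[t] for t in members])
        kim[idx] = w[np.ix_(idx, idx)].sum(axis=1)
        if lab in eigs:
            kme[idx] = kme_all.loc[members, lab].to_numpy()
        elif len(members) >= 2:
            try:
                grey_eig = module_eigengene(expr, members).to_numpy()
                kme[idx] = _corr_with(grey_eig)[idx]
            except ValueError:
                kme[idx] = 0.0

    stats = pd.DataFrame(
        {
            "module": assignment,
            "kIM": kim,
            "kME": kme,
            "clusterCoeff": cluster_coeff,
            "MAR": mar,
        },
        index=ids,
    )
    return NodeStatsTable(stats, kme_all)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; NaN when either vector is constant."""
    if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def compute_preservation(
    stats_a: NodeStatsTable,
    stats_b: NodeStatsTable,
    adj_a: AdjacencyNetwork,
    adj_b: AdjacencyNetwork,
    partition: ModulePartition,
) -> pd.DataFrame:
    """Per-module preservation correlations between two networks.

    Returns a DataFrame indexed by module label with the six ``cor.*``
    columns.  Modules with fewer than 3 members are flagged undefined (NaN)
    and excluded from downstream Z-scoring.  Symmetric in (A, B).
    """
    ids = adj_a.transcript_ids
    if not ids.equals(adj_b.transcript_ids):
        raise ValueError("networks must share the transcript set and order")
    pos = {t: i for i, t in enumerate(ids)}
    records = {}
    for lab in partition.labels:
        members = partition.members(lab)
        idx = np.array([pos[t] for t in members])
        if len(idx) < 3:
            records[lab] = {s: float("nan") for s in PRESERVATION_STATS}
            continue
        row = {}
        for stat, col in (
            ("cor.kIM", "kIM"),
            ("cor.kME", "kME"),
            ("cor.clusterCoeff", "clusterCoeff"),
            ("cor.MAR", "MAR"),
        ):
            row[stat] = _safe_corr(
                stats_a.stats.loc[members, col].to_numpy(),
                stats_b.stats.loc[members, col].to_numpy(),
            )
        row["cor.kMEall"] = _safe_corr(
            stats_a.kme_all.loc[members].to_numpy().ravel(),
            stats_b.kme_all.loc[members].to_numpy().ravel(),
        )
        iu = np.triu_indices(len(idx), k=1)
        row["cor.ADJ"] = _safe_corr(
            adj_a.weights[np.ix_(idx, idx)][iu],
            adj_b.weights[np.ix_(idx, idx)][iu],
        )
        records[lab] = row
    return pd.DataFrame(records).T[PRESERVATION_STATS].rename_axis("module")
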