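"""Core in-memory containers shared across the pipeline.

Expression data live in a :class:`pandas.DataFrame` with transcripts as rows
and samples as columns; the thin dataclasses here carry the sample-level
metadata (condition labels, dataset name) and enforce the invariants the
downstream network code relies on (unique ids, finite values, symmetric
adjacency in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reserved label for transcripts not assigned to any module.
GREY = "grey"


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but analytically degenerate
    (e.g. all node connectivities identical, zero-variance everywhere)."""


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, transcripts x samples.

    Parameters
    ----------
    values
        DataFrame indexed by transcript id with sample ids as columns.
    condition
        Per-sample condition label ("High"/"Low"), aligned to the columns.
    dataset
        Name of the dataset/selection this matrix belongs to (e.g. "F2").
    """

    values: pd.DataFrame
    condition: pd.Series | None = None
    dataset: str = ""

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate transcript ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        if self.condition is not None:
            self.condition = self.condition.reindex(self.values.columns)
            if self.condition.isna().any():
                raise ValueError("condition labels missing for some samples")

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        cond = self.condition.loc[sample_ids] if self.condition is not None else None
        return ExpressionMatrix(self.values.loc[:, sample_ids], cond, self.dataset)

    def subset_transcripts(self, transcript_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[transcript_ids], self.condition, self.dataset
        )


@dataclass
class DetectionTable:
    """Per-probe / per-sample detection p-values aligned to an ExpressionMatrix."""

    pvalues: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.pvalues.to_numpy()
        if ((vals < 0) | (vals > 1)).any() or not np.isfinite(vals).all():
            raise ValueError("detection p-values must lie in [0, 1]")


@dataclass
class AdjacencyNetwork:
    """Unsigned weighted adjacency a_ij = |corr(x_i, x_j)|**beta.

    Symmetric, zero diagonal, entries in [0, 1].
    """

    weights: np.ndarray
    transcript_ids: pd.Index
    beta: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("adjacency must be square")
        if w.shape[0] != len(self.transcript_ids):
            raise ValueError("adjacency size does not match transcript ids")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if (w < -1e-12).any() or (w > 1 + 1e-12).any():
            raise ValueError("adjacency entries must lie in [0, 1]")
        np.fill_diagonal(w, 0.0)
        self.weights = np.clip(w, 0.0, 1.0)
        self.transcript_ids = pd.Index(self.transcript_ids)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def connectivity(self) -> np.ndarray:
        """Whole-network connectivity k_i = sum_j a_ij (diagonal excluded)."""
        return self.weights.sum(axis=1)


@dataclass
class ModulePartition:
    """Transcript -> module label map; ``grey`` marks unassigned transcripts."""

    assignment: pd.Series

    def __post_init__(self) -> None:
        if self.assignment.index.duplicated().any():
            raise ValueError("duplicate transcript ids in partition")
        self.assignment = self.assignment.astype(str)

    @property
    def transcript_ids(self) -> pd.Index:
        return self.assignment.index

    @property
    def labels(self) -> list[str]:
        """Non-grey module labels in deterministic (sorted) order."""
        return sorted(set(self.assignment) - {GREY})

    def members(self, label: str) -> pd.Index:
        return self.assignment.index[self.assignment == label]

    def sizes(self) -> dict[str, int]:
        return {lab: int((self.assignment == lab).sum()) for lab in self.labels}


@dataclass
class GenotypeSet:
    """Marker dosages (0/1/2) for a set of samples with group labels."""

    dosages: pd.DataFrame  # samples x markers
    group: pd.Series  # per sample, "High"/"Low"

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy()
        if not np.isin(vals, (0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1 or 2")
        self.group = self.group.reindex(self.dosages.index)
        if self.group.isna().any():
            raise ValueError("group label missing for some samples")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def marker_ids(self) -> pd.Index:
        return self.dosages.columns
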