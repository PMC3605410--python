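"""Probe filtering and quantile normalization.

The filtering cascade mirrors standard microarray practice for network
construction: (1) drop probes not detected above background (detection
p < alpha) in at least a fixed fraction of samples, (2) keep the most
variable probes by coefficient of variation, (3) restrict all datasets to
the common surviving probe set so networks are built over identical nodes.
Normalization forces every sample onto the common distribution of mean
order statistics (quantile normalization); ties within a column receive the
mean of the reference values they span.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DetectionTable, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Per-dataset probe counts after each filtering stage."""

    n_input: dict[str, int]
    n_detected: dict[str, int]
    n_variable: dict[str, int]
    n_cv_undefined: dict[str, int]
    n_common: int

    def to_frame(self) -> pd.DataFrame:
        rows = {
            ds: {
                "input": self.n_input[ds],
                "detected": self.n_detected[ds],
                "variable": self.n_variable[ds],
                "cv_undefined_dropped": self.n_cv_undefined[ds],
                "common": self.n_common,
            }
            for ds in self.n_input
        }
        return pd.DataFrame(rows).T.rename_axis("dataset")


def filter_probes(
    expr_list: list[ExpressionMatrix],
    detection_list: list[DetectionTable] | None = None,
    detect_alpha: float = 0.01,
    min_detect_fraction: float = 0.25,
    cv_keep_fraction: float = 0.5,
    exclude_samples: list[str] | None = None,
    return_report: bool = False,
):
    """Detection filter, CV filter, then cross-dataset intersection.

    A probe survives detection when p < ``detect_alpha`` in at least
    ``ceil(min_detect_fraction * n_samples)`` samples; the CV filter then
    keeps the top ``cv_keep_fraction`` by sd/mean on the matrix's own scale.
    Probes with zero mean (undefined CV) are dropped with a logged count.
    ``exclude_samples`` removes pre-identified outlier samples first.
    """
    if not 0 < detect_alpha < 1:
        raise ValueError("detect_alpha must lie in (0, 1)")
    for frac, name in ((min_detect_fraction, "min_detect_fraction"),
                       (cv_keep_fraction, "cv_keep_fraction")):
        if not 0 < frac <= 1:
            raise ValueError(f"{name} must lie in (0, 1]")
    if detection_list is not None and len(detection_list) != len(expr_list):
        raise ValueError("one detection table per expression matrix required")

    report = FilterReport({}, {}, {}, {}, 0)
    surviving: list[pd.Index] = []
    filtered: list[ExpressionMatrix] = []
    for i, expr in enumerate(expr_list):
        ds = expr.dataset or f"dataset{i}"
        if exclude_samples:
            keep = [s for s in expr.sample_ids if s not in set(exclude_samples)]
            expr = expr.subset_samples(keep)
        report.n_input[ds] = len(expr.transcript_ids)

        probes = expr.transcript_ids
        if detection_list is not None:
            det = detection_list[i].pvalues.reindex(
                index=expr.transcript_ids, columns=expr.sample_ids
            )
            if det.isna().any().any():
                raise ValueError("detection table not aligned to expression matrix")
            need = math.ceil(min_detect_fraction * expr.n_samples)
            n_det = (det.to_numpy() < detect_alpha).sum(axis=1)
            probes = expr.transcript_ids[n_det >= need]
        report.n_detected[ds] = len(probes)

        sub = expr.values.loc[probes]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        defined = mean != 0
        n_undef = int((~defined).sum())
        if n_undef:
            logger.info("%s: dropping %d probes with undefined CV (mean 0)", ds, n_undef)
        report.n_cv_undefined[ds] = n_undef
        cv = (sd[defined] / mean[defined]).abs()
        n_keep = math.ceil(cv_keep_fraction * len(cv))
        kept = cv.sort_values(ascending=False, kind="stable").index[:n_keep]
        # preserve original probe order
        kept = probes[probes.isin(kept) & defined.reindex(probes, fill_value=False)]
        report.n_variable[ds] = len(kept)
        surviving.append(kept)
        filtered.append(expr)

    common = surviving[0]
    for s in surviving[1:]:
        common = common[common.isin(s)]
    if len(common) == 0:
        raise ValueError("no probes survive in all datasets (empty intersection)")
    report.n_common = len(common)

    out = [e.subset_transcripts(common) for e in filtered]
    return (out, report) if return_report else out


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the mean-order-statistic distribution.

    After normalization the sorted values of every column are identical
    (equal to the across-sample mean of order statistics); within-column
    ties receive the mean of the reference values they span, preserving
    rank order.
    """
    vals = expr.values.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    if not np.isfinite(vals).all():
        raise ValueError("expression values must be finite")

    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average the reference values spanned by each tie group
        sorted_col = col[order]
        start = 0
        for end in range(1, len(col) + 1):
            if end == len(col) or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    assigned[order[start:end]] = reference[start:end].mean()
                start = end
        out[:, j] = assigned
    values = pd.DataFrame(out, index=expr.transcript_ids, columns=expr.sample_ids)
    return ExpressionMatrix(values, expr.condition, expr.dataset)
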