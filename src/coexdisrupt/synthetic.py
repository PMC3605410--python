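"""Synthetic expression and genotype generators with known ground truth.

The expression generator draws each module from a one-factor model: a latent
per-sample "eigengene" factor, and member profiles ``loading * factor +
sqrt(1 - loading**2) * noise``.  Two conditions (High / Low) are drawn from
the same generative law except in designated *disrupted* modules, where the
Low condition rewires a fraction of members onto an independent factor —
changing the covariance (wiring) while leaving every marginal mean and
variance untouched, mirroring selection phenotypes where connectivity shifts
without large differential expression.

The genotype generator builds each chromosome copy as a first-order Markov
mosaic over inbred founder haplotypes (geometric block lengths), reads 0/1/2
dosages off a homozygous founder panel, and optionally biases the founder
distribution at designated "shifted" intervals differently in the High and
Low groups — the ground truth for allelic-imbalance scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeSet

#: Module labels follow the field's convention of arbitrary color names.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange",
]


@dataclass
class SyntheticExpressionBundle:
    """Paired-condition expression matrices with module ground truth."""

    expr_high: ExpressionMatrix
    expr_low: ExpressionMatrix
    truth_partition: pd.Series  # transcript -> module label
    disrupted_modules: set[str]
    seed: int

    def __post_init__(self) -> None:
        if not self.expr_high.transcript_ids.equals(self.expr_low.transcript_ids):
            raise ValueError("High and Low matrices must share the transcript index")
        if not set(self.disrupted_modules) <= set(self.truth_partition):
            raise ValueError("disrupted_modules must be labels of truth_partition")


@dataclass
class SyntheticGenotypeBundle:
    """Founder-mosaic genotypes with interval-level origin ground truth."""

    founder_panel: pd.DataFrame  # founders x markers, homozygous dosages {0, 2}
    genotypes: GenotypeSet  # samples x markers dosages with group labels
    truth_origin: np.ndarray  # samples x intervals x ploidy founder indices
    interval_bounds: list[tuple[int, int]]  # half-open marker ranges
    shifted_intervals: set[int]
    seed: int

    @property
    def founder_names(self) -> pd.Index:
        return self.founder_panel.index


def simulate_expression_pair(
    n_modules: int = 3,
    module_sizes: tuple[int, ...] | None = None,
    n_samples_per_condition: int = 40,
    loading: float = 0.7,
    disruption_fraction: float = 0.5,
    n_disrupted_modules: int = 1,
    hub_spread: float = 0.25,
    n_background: int = 0,
    baseline_mean: float = 7.0,
    seed: int = 0,
) -> SyntheticExpressionBundle:
    """Generate a High/Low expression pair with planted coexpression modules.

    Parameters
    ----------
    n_modules, module_sizes
        Number and sizes of planted modules (default 40 transcripts each).
    n_samples_per_condition
        Samples per condition; both conditions get the same n.
    loading
        Mean factor loading in [0, 1]; within-module pairwise correlation
        is ``loading**2`` in expectation.
    hub_spread
        Half-width of the per-member loading distribution: each member's
        loading is drawn uniformly from ``loading +/- min(hub_spread,
        loading, 1 - loading)`` (mean-preserving), once, shared by both
        conditions.  This gives every module a persistent hub hierarchy —
        the feature the connectivity-preservation statistics track in real
        coexpression data.  0 makes members exchangeable.
    disruption_fraction
        Fraction of each disrupted module's members rewired to an independent
        factor in the Low condition.  0 makes both conditions exchangeable.
    n_disrupted_modules
        How many modules (the first ones) to disrupt; ignored when
        ``disruption_fraction`` is 0.
    n_background
        Extra unassigned ("grey") pure-noise transcripts.
    baseline_mean
        Centre of per-transcript baseline log-intensities (shared between
        conditions so there is no differential expression by construction).
    """
    if module_sizes is None:
        module_sizes = (40,) * n_modules
    module_sizes = tuple(int(s) for s in module_sizes)
    if len(module_sizes) != n_modules:
        raise ValueError("module_sizes length must equal n_modules")
    if any(s < 3 for s in module_sizes):
        raise ValueError("module sizes must be >= 3")
    if n_samples_per_condition < 2 or n_background < 0:
        raise ValueError("counts must be non-negative (>= 2 samples/condition)")
    if not 0.0 <= loading <= 1.0:
        raise ValueError("loading must lie in [0, 1]")
    if not 0.0 <= disruption_fraction <= 1.0:
        raise ValueError("disruption_fraction must lie in [0, 1]")
    if n_modules > len(MODULE_COLORS):
        raise ValueError(f"at most {len(MODULE_COLORS)} modules supported")

    rng = np.random.default_rng(seed)
    n_tr = sum(module_sizes) + n_background
    n = n_samples_per_condition
    transcript_ids = pd.Index([f"T{i:05d}" for i in range(n_tr)], name="transcript")
    labels = np.repeat(MODULE_COLORS[:n_modules], module_sizes).tolist()
    labels += ["grey"] * n_background
    truth = pd.Series(labels, index=transcript_ids, name="module")

    disrupted: set[str] = set()
    if disruption_fraction > 0 and n_disrupted_modules > 0:
        disrupted = set(MODULE_COLORS[:min(n_disrupted_modules, n_modules)])

    baselines = rng.normal(baseline_mean, 1.0, size=n_tr)
    spread = min(hub_spread, loading, 1.0 - loading)
    member_loading = loading + rng.uniform(-spread, spread, size=n_tr)
    # rewired members draw a fresh loading in the Low condition: rewiring
    # replaces both their factor and their place in the hub hierarchy while
    # leaving the marginal mean and unit variance untouched
    rewired_loading = loading + rng.uniform(-spread, spread, size=n_tr)

    def draw_condition(rewire: bool) -> np.ndarray:
        out = np.empty((n_tr, n), dtype=float)
        row = 0
        for label, size in zip(MODULE_COLORS[:n_modules], module_sizes):
            factor = rng.normal(size=n)
            alt_factor = rng.normal(size=n)  # always drawn: keeps stream aligned
            n_rewired = (
                int(round(disruption_fraction * size))
                if rewire and label in disrupted
                else 0
            )
            for j in range(size):
                if j < n_rewired:
                    f, l = alt_factor, rewired_loading[row]
                else:
                    f, l = factor, member_loading[row]
                noise_sd = np.sqrt(max(0.0, 1.0 - l * l))
                out[row] = l * f + noise_sd * rng.normal(size=n)
                row += 1
        for _ in range(n_background):
            out[row] = rng.normal(size=n)
            row += 1
        return out

    high = draw_condition(rewire=False) + baselines[:, None]
    low = draw_condition(rewire=True) + baselines[:, None]

    def wrap(mat: np.ndarray, cond: str) -> ExpressionMatrix:
        cols = pd.Index([f"{cond}_{j:03d}" for j in range(n)], name="sample")
        values = pd.DataFrame(mat, index=transcript_ids, columns=cols)
        return ExpressionMatrix(values, pd.Series(cond, index=cols), dataset="synthetic")

    return SyntheticExpressionBundle(
        expr_high=wrap(high, "High"),
        expr_low=wrap(low, "Low"),
        truth_partition=truth,
        disrupted_modules=disrupted,
        seed=seed,
    )


def _draw_mosaic(
    rng: np.random.Generator,
    n_markers: int,
    interval_of_marker: np.ndarray,
    target_probs: np.ndarray,  # intervals x founders
    recomb_prob: float,
) -> np.ndarray:
    """One chromosome copy: founder index per marker.

    On a recombination event the new founder is drawn from the current
    interval's target distribution restricted to founders other than the
    current one, so block lengths are geometric with mean ``1/recomb_prob``.
    At boundaries where the target distribution changes (the edges of a
    shifted interval) the founder is re-drawn from the new distribution,
    modelling selection acting at that locus without bleeding the selected
    block into flanking intervals.
    """
    n_founders = target_probs.shape[1]
    path = np.empty(n_markers, dtype=np.int64)
    state = rng.choice(n_founders, p=target_probs[interval_of_marker[0]])
    for m in range(n_markers):
        iv = interval_of_marker[m]
        prev_iv = interval_of_marker[m - 1] if m > 0 else iv
        # re-draw whenever the target distribution changes across the
        # boundary (entering *or leaving* a shifted interval): keeps
        # non-shifted intervals distributionally identical between groups
        # instead of letting selected blocks bleed across the boundary
        if prev_iv != iv and not np.array_equal(
            target_probs[iv], target_probs[prev_iv]
        ):
            state = rng.choice(n_founders, p=target_probs[iv])
        elif m > 0 and rng.random() < recomb_prob:
            probs = target_probs[iv].copy()
            probs[state] = 0.0
            if probs.sum() > 0:
                state = rng.choice(n_founders, p=probs / probs.sum())
        path[m] = state
    return path


def simulate_genotypes(
    n_founders: int = 8,
    n_markers: int = 500,
    n_intervals: int = 25,
    n_samples_per_group: int = 50,
    recomb_prob: float = 0.05,
    shift_strength: float = 0.8,
    n_shifted_intervals: int = 2,
    ploidy: int = 2,
    seed: int = 0,
) -> SyntheticGenotypeBundle:
    """Generate founder-mosaic genotypes for two selected groups.

    Each sample carries ``ploidy`` independently drawn founder mosaics
    (default 2, unphased); dosages are the sum of the founder alleles.
    ``shift_strength`` mixes the uniform founder distribution with a point
    mass on a group-favoured founder at the shifted intervals (disjoint
    favoured founders for High and Low), producing the allele-frequency
    divergence that selection leaves behind.  ``ploidy=1`` gives a haploid
    mosaic whose per-interval origin truth is unambiguous.
    """
    if n_founders < 2 and n_founders != 1:
        raise ValueError("n_founders must be >= 1")
    if not 0.0 < recomb_prob < 1.0:
        raise ValueError("recomb_prob must lie in (0, 1)")
    if not 0.0 <= shift_strength <= 1.0:
        raise ValueError("shift_strength must lie in [0, 1]")
    if n_shifted_intervals > n_intervals:
        raise ValueError("shifted intervals exceed n_intervals")
    if n_markers < n_intervals:
        raise ValueError("need at least one marker per interval")
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")

    rng = np.random.default_rng(seed)
    founder_names = pd.Index([f"F{k}" for k in range(n_founders)], name="founder")
    marker_ids = pd.Index([f"M{m:05d}" for m in range(n_markers)], name="marker")
    # Homozygous inbred panel: allele 0/1 per founder/marker, dosage 0/2.
    alleles = rng.integers(0, 2, size=(n_founders, n_markers))
    if n_founders >= 2:
        # Guarantee every marker is polymorphic in the panel so mosaics are
        # identifiable; flip one founder at monomorphic markers.
        mono = np.where((alleles.min(0) == alleles.max(0)))[0]
        for m in mono:
            alleles[rng.integers(n_founders), m] ^= 1
    panel = pd.DataFrame(2 * alleles, index=founder_names, columns=marker_ids)

    bounds_idx = np.linspace(0, n_markers, n_intervals + 1, dtype=int)
    interval_bounds = [
        (int(bounds_idx[i]), int(bounds_idx[i + 1])) for i in range(n_intervals)
    ]
    interval_of_marker = np.repeat(
        np.arange(n_intervals), np.diff(bounds_idx)
    )
    shifted = set(range(n_shifted_intervals))

    uniform = np.full(n_founders, 1.0 / n_founders)

    def group_targets(favored: int) -> np.ndarray:
        probs = np.tile(uniform, (n_intervals, 1))
        if n_founders >= 2:
            for iv in shifted:
                point = np.zeros(n_founders)
                point[favored] = 1.0
                probs[iv] = (1 - shift_strength) * uniform + shift_strength * point
        return probs

    targets = {"High": group_targets(0), "Low": group_targets(1 % n_founders)}

    n_total = 2 * n_samples_per_group
    sample_ids = pd.Index(
        [f"{g}_{j:03d}" for g in ("High", "Low") for j in range(n_samples_per_group)],
        name="sample",
    )
    group = pd.Series(
        ["High"] * n_samples_per_group + ["Low"] * n_samples_per_group,
        index=sample_ids,
    )

    dosages = np.zeros((n_total, n_markers), dtype=np.int64)
    truth = np.empty((n_total, n_intervals, ploidy), dtype=np.int64)
    for s in range(n_total):
        probs = targets[group.iloc[s]]
        for copy in range(ploidy):
            path = _draw_mosaic(
                rng, n_markers, interval_of_marker, probs, recomb_prob
            )
            dosages[s] += alleles[path, np.arange(n_markers)]
            for iv, (a, b) in enumerate(interval_bounds):
                # majority founder over the interval's markers
                truth[s, iv, copy] = np.bincount(
                    path[a:b], minlength=n_founders
                ).argmax()
        if ploidy == 1:
            dosages[s] *= 2  # haploid mode reports homozygous dosages

    genos = GenotypeSet(
        pd.DataFrame(dosages, index=sample_ids, columns=marker_ids), group
    )
    return SyntheticGenotypeBundle(
        founder_panel=panel,
        genotypes=genos,
        truth_origin=truth,
        interval_bounds=interval_bounds,
        shifted_intervals=shifted,
        seed=seed,
    )
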