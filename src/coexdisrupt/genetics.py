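"""Genotype-side analyses for two selected lines.

- AMOVA: genome-wide genetic differentiation between groups, partitioning
  pairwise Manhattan distances on 0/1/2 dosage vectors into among- and
  within-group sums of squares, with a permutation F-test.
- Classical (Torgerson) multidimensional scaling for visualising the
  pairwise-distance structure.
- Founder-origin inference: each sample chromosome is modelled as a hidden
  Markov chain over founder states; emissions reward dosage agreement with
  the (homozygous) founder panel, transitions allow recombination switches.
  Forward-backward posteriors are averaged within genomic intervals.
- Allelic imbalance: per interval, the argmax founder counts per group form
  a 2 x F contingency table tested with Fisher's exact test (exact for
  2 x 2, Monte Carlo with fixed margins otherwise), BH-adjusted across
  intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln

from .containers import GenotypeSet
from .diffexpr import adjust_pvalues


@dataclass
class AmovaResult:
    f_statistic: float
    p_value: float
    ss_among: float
    ss_within: float
    n_perm: int


@dataclass
class FounderOriginPosterior:
    """Per sample x interval x founder posterior probabilities."""

    probabilities: np.ndarray  # samples x intervals x founders
    sample_ids: pd.Index
    founder_names: pd.Index
    interval_bounds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        sums = self.probabilities.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("posteriors must sum to 1 per sample/interval")

    @property
    def argmax(self) -> np.ndarray:
        """Most probable founder index per sample/interval."""
        return self.probabilities.argmax(axis=2)


def manhattan_distances(genos: GenotypeSet) -> np.ndarray:
    """Pairwise Manhattan (city-block) distances between dosage vectors."""
    return squareform(pdist(genos.dosages.to_numpy(float), metric="cityblock"))


def _amova_f(d_sq: np.ndarray, group_idx: list[np.ndarray]) -> float:
    """F from the squared-distance AMOVA partition.

    SS_total = sum_{i<j} d^2_ij / N; SS_within = sum over groups of the
    analogous within-group term; F = (SS_among/(k-1)) / (SS_within/(N-k)).
    """
    n = d_sq.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d_sq[iu].sum() / n
    ss_within = 0.0
    for idx in group_idx:
        sub = d_sq[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    k = len(group_idx)
    if ss_within <= 0:
        return np.inf
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def amova(genos: GenotypeSet, n_perm: int = 999, seed: int = 0) -> AmovaResult:
    """Permutation F-test of among-group vs within-group genetic distance."""
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    groups = genos.group
    levels = sorted(set(groups))
    if any((groups == g).sum() < 2 for g in levels):
        raise ValueError("each group needs >= 2 samples")
    d = manhattan_distances(genos)
    d_sq = d**2
    labels = groups.to_numpy()
    group_idx = [np.where(labels == g)[0] for g in levels]
    obs = _amova_f(d_sq, group_idx)

    rng = np.random.default_rng(seed)
    sizes = [len(i) for i in group_idx]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(d.shape[0])
        idx, start = [], 0
        for s in sizes:
            idx.append(perm[start:start + s])
            start += s
        if _amova_f(d_sq, idx) >= obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)

    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d_sq[iu].sum() / n
    ss_within = sum(
        d_sq[np.ix_(i, i)][np.triu_indices(len(i), k=1)].sum() / len(i)
        for i in group_idx
    )
    return AmovaResult(
        f_statistic=float(obs),
        p_value=float(p),
        ss_among=float(ss_total - ss_within),
        ss_within=float(ss_within),
        n_perm=n_perm,
    )


def mds_embed(distances: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a symmetric distance matrix.

    Double-centres -0.5 * D^2, takes the top-k eigenvectors scaled by the
    square roots of their eigenvalues.  Negative eigenvalues (non-Euclidean
    input) are truncated with a warning.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_pos = int((eigval > 1e-10).sum())
    if k > n_pos:
        if np.allclose(d, 0):
            return np.zeros((n, k))
        raise ValueError(f"k={k} exceeds the {n_pos} positive eigenvalues")
    if (eigval < -1e-8 * max(1.0, abs(eigval[0]))).any():
        import warnings

        warnings.warn("negative eigenvalues truncated (non-Euclidean distances)")
    return eigvec[:, :k] * np.sqrt(eigval[:k])


def _forward_backward(
    log_emission: np.ndarray,  # markers x states
    stay: float,
) -> np.ndarray:
    """Posterior state probabilities of a uniform-switch Markov chain.

    Transition: stay with probability ``stay``, otherwise uniform over the
    other states.  Scaled forward-backward, uniform initial distribution.
    """
    n_markers, n_states = log_emission.shape
    if n_states == 1:
        return np.ones((n_markers, 1))
    switch = (1.0 - stay) / (n_states - 1)
    emission = np.exp(log_emission - log_emission.max(axis=1, keepdims=True))

    alpha = np.empty((n_markers, n_states))
    scale = np.empty(n_markers)
    alpha[0] = emission[0] / n_states
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for m in range(1, n_markers):
        pred = alpha[m - 1] * (stay - switch) + switch * alpha[m - 1].sum()
        alpha[m] = pred * emission[m]
        scale[m] = alpha[m].sum()
        alpha[m] /= scale[m]

    beta = np.empty((n_markers, n_states))
    beta[-1] = 1.0
    for m in range(n_markers - 2, -1, -1):
        msg = beta[m + 1] * emission[m + 1]
        beta[m] = (msg * (stay - switch) + switch * msg.sum()) / scale[m + 1]

    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post


def infer_founder_origin(
    genos: GenotypeSet,
    founder_panel: pd.DataFrame,
    error_rate: float = 0.01,
    switch_prob: float = 0.05,
    interval_bounds: list[tuple[int, int]] | None = None,
    diploid: bool = False,
) -> FounderOriginPosterior:
    """Founder-of-origin posteriors per sample and genomic interval.

    Haploid mode (default) treats each sample as one founder mosaic: the
    emission probability is ``1 - error_rate`` when the sample dosage equals
    the founder's homozygous dosage and ``error_rate`` otherwise (so
    heterozygous sites are uninformative).  Diploid mode scores unordered
    founder pairs against the summed founder alleles and marginalises the
    pair posterior to single founders.  Posteriors are averaged over each
    interval's markers; intervals default to single markers.
    """
    if not 0.0 < error_rate < 0.5:
        raise ValueError("error_rate must lie in (0, 0.5)")
    if not 0.0 < switch_prob < 1.0:
        raise ValueError("switch_prob must lie in (0, 1)")
    if not genos.marker_ids.equals(pd.Index(founder_panel.columns)):
        raise ValueError("marker sets of samples and founder panel differ")
    panel = founder_panel.to_numpy(float)
    if not np.isin(panel, (0, 2)).all():
        raise ValueError("founder panel must be homozygous (dosages 0 or 2)")
    n_founders, n_markers = panel.shape
    if interval_bounds is None:
        interval_bounds = [(m, m + 1) for m in range(n_markers)]
    dosages = genos.dosages.to_numpy(float)
    n_samples = dosages.shape[0]
    stay = 1.0 - switch_prob
    log_hit, log_miss = math.log(1 - error_rate), math.log(error_rate)

    if diploid:
        pairs = [
            (a, b) for a in range(n_founders) for b in range(a, n_founders)
        ]
        pair_dosage = np.array(
            [panel[a] / 2 + panel[b] / 2 for a, b in pairs]
        )  # pairs x markers, in {0,1,2}
    out = np.zeros((n_samples, len(interval_bounds), n_founders))
    for s in range(n_samples):
        if diploid:
            match = pair_dosage == dosages[s][None, :]
            log_em = np.where(match, log_hit, log_miss).T  # markers x pairs
            post_pairs = _forward_backward(log_em, stay)
            post = np.zeros((n_markers, n_founders))
            for p_idx, (a, b) in enumerate(pairs):
                post[:, a] += 0.5 * post_pairs[:, p_idx]
                post[:, b] += 0.5 * post_pairs[:, p_idx]
        else:
            match = panel == dosages[s][None, :]
            log_em = np.where(match, log_hit, log_miss).T  # markers x founders
            post = _forward_backward(log_em, stay)
        for iv, (a, b) in enumerate(interval_bounds):
            out[s, iv] = post[a:b].mean(axis=0)
    out /= out.sum(axis=2, keepdims=True)
    return FounderOriginPosterior(
        probabilities=out,
        sample_ids=genos.sample_ids,
        founder_names=pd.Index(founder_panel.index),
        interval_bounds=list(interval_bounds),
    )


def _log_table_prob(table: np.ndarray) -> float:
    """Log probability of an R x C table under fixed margins
    (multivariate hypergeometric)."""
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(row + 1).sum()
        + gammaln(col + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def fisher_table_test(
    table: np.ndarray, n_mc: int = 10_000, seed: int = 0
) -> float:
    """Two-sided Fisher exact p for a 2 x C table.

    Exact for 2 x 2 (scipy); for wider tables a Monte-Carlo test with fixed
    margins using the table-probability ordering: p = (1 + #{simulated
    tables at most as probable as observed}) / (n_mc + 1).
    """
    table = np.asarray(table, dtype=np.int64)
    if table.sum() == 0:
        raise ValueError("contingency table has zero counts")
    # drop empty columns: they carry no information and break 2x2 dispatch
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return 1.0
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if n_mc < 10_000:
        raise ValueError("n_mc must be >= 10000 for tables wider than 2x2")
    rng = np.random.default_rng(seed)
    obs_logp = _log_table_prob(table)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    # permute column labels of the underlying observations; margins fixed
    pool = np.repeat(np.arange(table.shape[1]), col)
    hits = 0
    tol = 1e-9
    for _ in range(n_mc):
        rng.shuffle(pool)
        sim = np.stack(
            [
                np.bincount(pool[: row[0]], minlength=table.shape[1]),
                np.bincount(pool[row[0]:], minlength=table.shape[1]),
            ]
        )
        if _log_table_prob(sim) <= obs_logp + tol:
            hits += 1
    return (1 + hits) / (n_mc + 1)


def allele_imbalance_test(
    origins: FounderOriginPosterior,
    groups: pd.Series,
    fdr_threshold: float = 0.1,
    n_mc: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Founder-origin imbalance between groups, per genomic interval.

    Builds the 2 x F argmax-founder count table at every interval, computes
    a Fisher p (exact or Monte Carlo), BH-adjusts across intervals and flags
    intervals at q < ``fdr_threshold``.
    """
    groups = groups.reindex(origins.sample_ids)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    argmax = origins.argmax
    n_founders = len(origins.founder_names)
    rng = np.random.default_rng(seed)
    rows = []
    for iv in range(argmax.shape[1]):
        counts = np.stack(
            [
                np.bincount(argmax[groups.to_numpy() == g, iv], minlength=n_founders)
                for g in levels
            ]
        )
        p = fisher_table_test(
            counts, n_mc=n_mc, seed=int(rng.integers(2**31 - 1))
        )
        row = {"interval": iv, "p": p}
        for f, name in enumerate(origins.founder_names):
            row[f"{levels[0]}_{name}"] = int(counts[0, f])
            row[f"{levels[1]}_{name}"] = int(counts[1, f])
        rows.append(row)
    scan = pd.DataFrame(rows).set_index("interval")
    scan["q"] = adjust_pvalues(scan["p"].to_numpy(), method="BH")
    scan["flagged"] = scan["q"] < fdr_threshold
    return scan
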