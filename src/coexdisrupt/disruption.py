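"""Module-disruption Z-scores against a sample-bootstrap empirical null.

Two networks built from the High and Low samples will differ even without
any biological signal, simply from sampling noise.  The null model here
quantifies that chance level *empirically*: each of ``n_boot`` iterations
pools all samples from both conditions, resamples two pseudo-condition
sample sets of the original sizes (bootstrap over samples, not over network
nodes), builds both networks at the same soft threshold, and records every
per-module preservation statistic plus each transcript's intramodular
connectivity difference.  Observed High-vs-Low values are then standardised:

    Z = (obs_a - mu_a) / sigma_a

with mu_a, sigma_a the mean and standard deviation over the null draws.
Preservation between genuinely different conditions is *lower* than between
mixed-sample networks, so disruption shows up as negative Z; modules with
cor.kIM Z below -2 are flagged disrupted, and transcripts with |Z| > 2 are
flagged as significantly changed in connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AdjacencyNetwork, ExpressionMatrix, ModulePartition
from .netstats import PRESERVATION_STATS, compute_node_statistics, compute_preservation
from .network import build_adjacency


@dataclass
class NullDistribution:
    """Empirical null draws for every module/statistic and transcript."""

    module_values: dict[str, pd.DataFrame]  # stat -> (n_boot x modules)
    kim_diff: pd.DataFrame  # n_boot x transcripts
    n_boot: int
    seed: int

    def module_mu_sigma(self, stat: str) -> tuple[pd.Series, pd.Series]:
        draws = self.module_values[stat]
        return draws.mean(axis=0), draws.std(axis=0, ddof=1)

    def transcript_mu_sigma(self) -> tuple[pd.Series, pd.Series]:
        return self.kim_diff.mean(axis=0), self.kim_diff.std(axis=0, ddof=1)


@dataclass
class DisruptionResult:
    """Z-scores with the threshold rules already applied."""

    module_z: pd.DataFrame  # modules x six cor.* statistics
    transcript_z: pd.Series
    disrupted_modules: list[str]
    changed_transcripts: list[str]
    z_threshold: float
    degenerate: set[str] = field(default_factory=set)  # "module/stat" with sigma=0


def _pair_stats(
    x_high: np.ndarray,
    x_low: np.ndarray,
    template: ExpressionMatrix,
    partition: ModulePartition,
    beta: float,
) -> tuple[pd.DataFrame, pd.Series]:
    """Preservation record and per-transcript kIM difference for one
    High/Low matrix pair (columns may be bootstrap resamples)."""
    ids = template.transcript_ids

    def wrap(x: np.ndarray, tag: str) -> ExpressionMatrix:
        cols = pd.Index([f"{tag}{j}" for j in range(x.shape[1])])
        return ExpressionMatrix(pd.DataFrame(x, index=ids, columns=cols))

    eh, el = wrap(x_high, "h"), wrap(x_low, "l")
    adj_h = build_adjacency(eh, beta)
    adj_l = build_adjacency(el, beta)
    stats_h = compute_node_statistics(adj_h, eh, partition)
    stats_l = compute_node_statistics(adj_l, el, partition)
    pres = compute_preservation(stats_h, stats_l, adj_h, adj_l, partition)
    kim_diff = stats_h.stats["kIM"] - stats_l.stats["kIM"]
    return pres, kim_diff


def observed_disruption_inputs(
    expr_high: ExpressionMatrix,
    expr_low: ExpressionMatrix,
    partition: ModulePartition,
    beta: float = 10.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Observed High-vs-Low preservation record and kIM differences."""
    _check_pair(expr_high, expr_low, partition)
    return _pair_stats(
        expr_high.values.to_numpy(float),
        expr_low.values.to_numpy(float),
        expr_high,
        partition,
        beta,
    )


def build_null(
    expr_high: ExpressionMatrix,
    expr_low: ExpressionMatrix,
    partition: ModulePartition,
    beta: float = 10.0,
    n_boot: int = 200,
    seed: int = 0,
    null_mode: str = "bootstrap",
) -> NullDistribution:
    """Mixed-sample empirical null (default 200 network pairs).

    ``null_mode='bootstrap'`` resamples with replacement from the pooled
    samples; ``'permute'`` splits a random permutation of the pool into two
    pseudo-conditions of the original sizes.  An iteration producing a
    constant transcript in either pseudo-matrix is redrawn (max 10 tries).
    """
    _check_pair(expr_high, expr_low, partition)
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50")
    if null_mode not in ("bootstrap", "permute"):
        raise ValueError("null_mode must be 'bootstrap' or 'permute'")
    rng = np.random.default_rng(seed)
    xh = expr_high.values.to_numpy(float)
    xl = expr_low.values.to_numpy(float)
    pool = np.concatenate([xh, xl], axis=1)
    n_high, n_low = xh.shape[1], xl.shape[1]
    n_pool = n_high + n_low

    labels = partition.labels
    module_values = {
        s: np.empty((n_boot, len(labels))) for s in PRESERVATION_STATS
    }
    kim_diff = np.empty((n_boot, len(expr_high.transcript_ids)))

    for b in range(n_boot):
        for attempt in range(10):
            if null_mode == "bootstrap":
                hi = pool[:, rng.integers(0, n_pool, size=n_high)]
                lo = pool[:, rng.integers(0, n_pool, size=n_low)]
            else:
                perm = rng.permutation(n_pool)
                hi = pool[:, perm[:n_high]]
                lo = pool[:, perm[n_high:]]
            if hi.std(axis=1).min() > 0 and lo.std(axis=1).min() > 0:
                break
        else:
            raise RuntimeError(
                "could not draw a non-degenerate pseudo-sample in 10 attempts"
            )
        pres, kd = _pair_stats(hi, lo, expr_high, partition, beta)
        for s in PRESERVATION_STATS:
            module_values[s][b] = pres[s].to_numpy()
        kim_diff[b] = kd.to_numpy()

    return NullDistribution(
        module_values={
            s: pd.DataFrame(v, columns=labels) for s, v in module_values.items()
        },
        kim_diff=pd.DataFrame(kim_diff, columns=expr_high.transcript_ids),
        n_boot=n_boot,
        seed=seed,
    )


def score_disruption(
    observed: pd.DataFrame,
    observed_kim_diff: pd.Series,
    null: NullDistribution,
    z_threshold: float = 2.0,
    flag_stat: str = "cor.kIM",
) -> DisruptionResult:
    """Standardise observed values against the null; apply threshold rules.

    A module is flagged disrupted when its ``flag_stat`` Z is below
    ``-z_threshold``; a transcript is flagged changed when its |Z| exceeds
    ``z_threshold``.  Cells with a degenerate null (sigma = 0) are reported
    as NaN and listed in ``degenerate`` — never silently zero.
    """
    degenerate: set[str] = set()
    module_z = {}
    for stat in PRESERVATION_STATS:
        mu, sigma = null.module_mu_sigma(stat)
        obs = observed[stat]
        z = pd.Series(np.nan, index=obs.index)
        for mod in obs.index:
            if not np.isfinite(obs[mod]) or not np.isfinite(mu.get(mod, np.nan)):
                degenerate.add(f"{mod}/{stat}")
                continue
            if sigma[mod] == 0:
                degenerate.add(f"{mod}/{stat}")
                continue
            z[mod] = (obs[mod] - mu[mod]) / sigma[mod]
        module_z[stat] = z
    module_z = pd.DataFrame(module_z)[PRESERVATION_STATS].rename_axis("module")

    mu_t, sigma_t = null.transcript_mu_sigma()
    with np.errstate(invalid="ignore", divide="ignore"):
        tz = (observed_kim_diff - mu_t) / sigma_t
    zero_sigma = sigma_t == 0
    if zero_sigma.any():
        for t in sigma_t.index[zero_sigma]:
            degenerate.add(f"{t}/kIM")
        tz[zero_sigma] = np.nan

    flag_z = module_z[flag_stat]
    disrupted = [m for m in flag_z.index if flag_z[m] < -z_threshold]
    changed = [t for t in tz.index if np.isfinite(tz[t]) and abs(tz[t]) > z_threshold]
    return DisruptionResult(
        module_z=module_z,
        transcript_z=tz,
        disrupted_modules=disrupted,
        changed_transcripts=changed,
        z_threshold=z_threshold,
        degenerate=degenerate,
    )


def disruption_analysis(
    expr_high: ExpressionMatrix,
    expr_low: ExpressionMatrix,
    partition: ModulePartition,
    beta: float = 10.0,
    n_boot: int = 200,
    seed: int = 0,
    z_threshold: float = 2.0,
    null_mode: str = "bootstrap",
) -> DisruptionResult:
    """Observed statistics + empirical null + Z-scoring in one call."""
    observed, kim_diff = observed_disruption_inputs(
        expr_high, expr_low, partition, beta
    )
    null = build_null(
        expr_high, expr_low, partition, beta, n_boot, seed, null_mode
    )
    return score_disruption(observed, kim_diff, null, z_threshold)


def _check_pair(
    expr_high: ExpressionMatrix,
    expr_low: ExpressionMatrix,
    partition: ModulePartition,
) -> None:
    if not expr_high.transcript_ids.equals(expr_low.transcript_ids):
        raise ValueError("High and Low matrices must share transcripts")
    if not expr_high.transcript_ids.equals(partition.transcript_ids):
        raise ValueError("partition must cover the shared transcript set")
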