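"""End-to-end orchestration: synthetic or file inputs through preprocessing,
network construction, disruption scoring, differential expression and the
genotype analyses, with per-stage TSV outputs and a machine-readable summary.

Every stochastic stage consumes a sub-seed deterministically derived from
the master seed, so a run is byte-reproducible from its config echo.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cdio
from .containers import ExpressionMatrix, GenotypeSet, ModulePartition
from .diffexpr import enrichment_table, moderated_t_test, read_gene_sets_tsv
from .disruption import build_null, observed_disruption_inputs, score_disruption
from .genetics import (
    allele_imbalance_test,
    amova,
    infer_founder_origin,
    manhattan_distances,
    mds_embed,
)
from .netstats import compute_node_statistics
from .network import build_adjacency, consensus_adjacency, detect_modules
from .preprocess import quantile_normalize
from .synthetic import simulate_expression_pair, simulate_genotypes

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative configuration of a full run.

    Leave the path fields empty to generate synthetic inputs from the
    ``sim_*`` parameters.
    """

    out_dir: str = "run_out"
    seed: int = 0
    # network / disruption parameters
    beta: float = 10.0
    min_module_size: int = 30
    merge_cut: float = 0.25
    n_boot: int = 200
    z_threshold: float = 2.0
    null_mode: str = "bootstrap"
    quantile_norm: bool = True
    # thresholds
    de_fdr: float = 0.1
    imbalance_fdr: float = 0.1
    # file inputs (optional)
    expr_high_path: str = ""
    expr_low_path: str = ""
    genotypes_path: str = ""
    genotype_labels_path: str = ""
    founder_panel_path: str = ""
    gene_sets_path: str = ""
    # synthetic generation parameters (used when no files given)
    sim_n_modules: int = 3
    sim_module_size: int = 40
    sim_n_samples: int = 40
    sim_loading: float = 0.7
    sim_disruption_fraction: float = 0.5
    sim_n_disrupted: int = 1
    sim_genotypes: bool = True
    sim_n_founders: int = 8
    sim_n_markers: int = 500
    sim_n_intervals: int = 25
    sim_shift_strength: float = 0.8

    def validate(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.merge_cut < 1:
            raise ValueError("merge_cut must lie in (0, 1)")
        if self.n_boot < 50:
            raise ValueError("n_boot must be >= 50")
        for name in ("de_fdr", "imbalance_fdr"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, params: dict) -> "RunConfig":
        return cls(**params)


def _sub_seeds(master: int, n: int) -> list[int]:
    """Derive n independent sub-seeds (< 2**31) from the master seed."""
    states = np.random.SeedSequence(master).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in states]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the machine-readable summary dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cdio.write_config_echo(config.to_dict(), out / "config_echo.txt")
    seeds = dict(
        zip(
            ["simulate_expr", "simulate_geno", "null", "imbalance", "amova"],
            _sub_seeds(config.seed, 5),
        )
    )
    summary: dict = {"seed": config.seed, "stages": []}

    def stage(name: str):
        logger.info("stage=%s sub_seed=%s", name, seeds.get(name, "-"))
        summary["stages"].append(name)

    # ---- inputs -----------------------------------------------------------
    genos: GenotypeSet | None = None
    founder_panel = None
    geno_bundle = None
    try:
        stage("inputs")
        if config.expr_high_path:
            expr_high = cdio.read_expression(config.expr_high_path, dataset="High")
            expr_low = cdio.read_expression(config.expr_low_path, dataset="Low")
            truth = None
        else:
            bundle = simulate_expression_pair(
                n_modules=config.sim_n_modules,
                module_sizes=(config.sim_module_size,) * config.sim_n_modules,
                n_samples_per_condition=config.sim_n_samples,
                loading=config.sim_loading,
                disruption_fraction=config.sim_disruption_fraction,
                n_disrupted_modules=config.sim_n_disrupted,
                seed=seeds["simulate_expr"],
            )
            expr_high, expr_low, truth = (
                bundle.expr_high,
                bundle.expr_low,
                bundle.truth_partition,
            )
            cdio.write_expression(expr_high, out / "expr_high.tsv")
            cdio.write_expression(expr_low, out / "expr_low.tsv")
            truth.rename("module").rename_axis("transcript").to_csv(
                out / "truth_partition.tsv", sep="\t"
            )
            summary["planted_disrupted_modules"] = sorted(bundle.disrupted_modules)
        if config.genotypes_path:
            genos = cdio.read_genotypes(
                config.genotypes_path, config.genotype_labels_path
            )
            if config.founder_panel_path:
                founder_panel = cdio.read_matrix_tsv(config.founder_panel_path).T
        elif not config.expr_high_path and config.sim_genotypes:
            geno_bundle = simulate_genotypes(
                n_founders=config.sim_n_founders,
                n_markers=config.sim_n_markers,
                n_intervals=config.sim_n_intervals,
                shift_strength=config.sim_shift_strength,
                seed=seeds["simulate_geno"],
            )
            genos, founder_panel = geno_bundle.genotypes, geno_bundle.founder_panel
            cdio.write_genotypes(
                genos, out / "genotypes.tsv", out / "genotype_groups.tsv"
            )
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("inputs", exc) from exc

    # ---- preprocessing ----------------------------------------------------
    try:
        stage("preprocess")
        if config.quantile_norm:
            expr_high = quantile_normalize(expr_high)
            expr_low = quantile_normalize(expr_low)
    except Exception as exc:
        raise StageError("preprocess", exc) from exc

    # ---- networks and modules --------------------------------------------
    try:
        stage("network")
        adj_high = build_adjacency(expr_high, config.beta)
        adj_low = build_adjacency(expr_low, config.beta)
        consensus = consensus_adjacency([adj_high, adj_low])
        combined = ExpressionMatrix(
            pd.concat([expr_high.values, expr_low.values], axis=1)
        )
        partition = detect_modules(
            consensus,
            combined,
            min_module_size=config.min_module_size,
            merge_cut=config.merge_cut,
        )
        cdio.write_partition(partition, out / "module_partition.tsv")
        summary["n_modules"] = len(partition.labels)
        summary["module_sizes"] = partition.sizes()
    except Exception as exc:
        raise StageError("network", exc) from exc

    # ---- disruption -------------------------------------------------------
    try:
        stage("disruption")
        observed, kim_diff = observed_disruption_inputs(
            expr_high, expr_low, partition, config.beta
        )
        null = build_null(
            expr_high,
            expr_low,
            partition,
            beta=config.beta,
            n_boot=config.n_boot,
            seed=seeds["null"],
            null_mode=config.null_mode,
        )
        result = score_disruption(
            observed, kim_diff, null, z_threshold=config.z_threshold
        )
        result.module_z.to_csv(out / "module_disruption_z.tsv", sep="\t")
        stats_high = compute_node_statistics(adj_high, expr_high, partition)
        stats_low = compute_node_statistics(adj_low, expr_low, partition)
        table2 = _transcript_table(
            partition, stats_high, stats_low, result.transcript_z
        )
        summary["disrupted_modules"] = result.disrupted_modules
        summary["n_changed_transcripts"] = len(result.changed_transcripts)
    except Exception as exc:
        raise StageError("disruption", exc) from exc

    # ---- differential expression -----------------------------------------
    try:
        stage("diffexpr")
        combined_cond = pd.concat(
            [
                pd.Series("High", index=expr_high.sample_ids),
                pd.Series("Low", index=expr_low.sample_ids),
            ]
        )
        de = moderated_t_test(
            ExpressionMatrix(
                pd.concat([expr_high.values, expr_low.values], axis=1),
                combined_cond,
            )
        )
        de.to_csv(out / "differential_expression.tsv", sep="\t")
        summary["n_de_transcripts"] = int((de["q"] < config.de_fdr).sum())
    except Exception as exc:
        raise StageError("diffexpr", exc) from exc

    # ---- enrichment -------------------------------------------------------
    if config.gene_sets_path:
        try:
            stage("enrichment")
            sets = read_gene_sets_tsv(config.gene_sets_path)
            enr = enrichment_table(partition.assignment, sets)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            summary["n_enriched"] = int((enr["p_adj"] < 0.05).sum())
        except Exception as exc:
            raise StageError("enrichment", exc) from exc

    # ---- genetics ---------------------------------------------------------
    scan = None
    if genos is not None:
        try:
            stage("genetics")
            am = amova(genos, n_perm=999, seed=seeds["amova"])
            coords = mds_embed(manhattan_distances(genos), k=2)
            pd.DataFrame(
                coords, index=genos.sample_ids, columns=["mds1", "mds2"]
            ).to_csv(out / "mds_coordinates.tsv", sep="\t")
            summary["amova_f"] = am.f_statistic
            summary["amova_p"] = am.p_value
            if founder_panel is not None:
                bounds = (
                    geno_bundle.interval_bounds if geno_bundle is not None else None
                )
                origins = infer_founder_origin(
                    genos, founder_panel, interval_bounds=bounds
                )
                scan = allele_imbalance_test(
                    origins,
                    genos.group,
                    fdr_threshold=config.imbalance_fdr,
                    seed=seeds["imbalance"],
                )
                scan.to_csv(out / "allele_imbalance.tsv", sep="\t")
                summary["n_imbalanced_intervals"] = int(scan["flagged"].sum())
        except Exception as exc:
            raise StageError("genetics", exc) from exc

    table2.to_csv(out / "transcript_connectivity.tsv", sep="\t")
    if truth is not None:
        summary["truth_modules"] = sorted(set(truth) - {"grey"})
    summary_json = json.dumps(summary, indent=2, sort_keys=True)
    (out / "summary.json").write_text(summary_json + "\n")
    return summary


def _transcript_table(
    partition: ModulePartition,
    stats_high,
    stats_low,
    transcript_z: pd.Series,
) -> pd.DataFrame:
    """Per-transcript table: module, connectivity rank in each network
    (rank 1 = highest kIM within the module) and the connectivity-change Z."""
    rows = pd.DataFrame(
        {
            "module": partition.assignment,
            "kIM_high": stats_high.stats["kIM"],
            "kIM_low": stats_low.stats["kIM"],
            "z": transcript_z,
        }
    )
    rows["rank_high"] = (
        rows.groupby("module")["kIM_high"].rank(ascending=False, method="min")
    ).astype(int)
    rows["rank_low"] = (
        rows.groupby("module")["kIM_low"].rank(ascending=False, method="min")
    ).astype(int)
    return rows.rename_axis("transcript")
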