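"""Tab-delimited readers and writers for every pipeline artefact.

All on-disk formats are plain TSV with a header row: expression and
detection tables carry transcripts as rows and sample ids as columns;
genotype dosage matrices carry markers as rows and sample ids as columns
(with a sidecar two-column group-label file); partitions and truth label
maps are two-column (transcript, module).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AdjacencyNetwork, ExpressionMatrix, GenotypeSet, ModulePartition


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: ExpressionMatrix, path, labels_path=None) -> None:
    write_matrix_tsv(expr.values, path)
    if labels_path is not None and expr.condition is not None:
        expr.condition.rename("condition").rename_axis("sample").to_csv(
            labels_path, sep="\t"
        )


def read_expression(path, labels_path=None, dataset: str = "") -> ExpressionMatrix:
    values = read_matrix_tsv(path)
    condition = None
    if labels_path is not None:
        condition = pd.read_csv(labels_path, sep="\t", index_col=0)["condition"]
    return ExpressionMatrix(values, condition, dataset)


def write_partition(partition: ModulePartition, path) -> None:
    partition.assignment.rename("module").rename_axis("transcript").to_csv(
        path, sep="\t"
    )


def read_partition(path) -> ModulePartition:
    return ModulePartition(pd.read_csv(path, sep="\t", index_col=0)["module"])


def write_adjacency(adj: AdjacencyNetwork, path) -> None:
    df = pd.DataFrame(
        adj.weights, index=adj.transcript_ids, columns=adj.transcript_ids
    )
    with open(path, "w") as fh:
        fh.write(f"# beta={adj.beta}\n")
        df.to_csv(fh, sep="\t")


def read_adjacency(path) -> AdjacencyNetwork:
    with open(path) as fh:
        header = fh.readline()
        beta = float(header.strip().split("beta=")[1]) if "beta=" in header else 1.0
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return AdjacencyNetwork(df.to_numpy(float), df.index, beta)


def write_edge_list(adj: AdjacencyNetwork, path, threshold: float = 0.0) -> None:
    """Weighted edge list (node_a, node_b, weight), upper triangle only."""
    ids = adj.transcript_ids
    iu = np.triu_indices(adj.n_nodes, k=1)
    w = adj.weights[iu]
    keep = w >= threshold
    pd.DataFrame(
        {
            "node_a": ids[iu[0][keep]],
            "node_b": ids[iu[1][keep]],
            "weight": w[keep],
        }
    ).to_csv(path, sep="\t", index=False)


def write_genotypes(genos: GenotypeSet, path, labels_path=None) -> None:
    # markers as rows, samples as columns (transposed relative to memory)
    genos.dosages.T.to_csv(path, sep="\t")
    if labels_path is not None:
        genos.group.rename("group").rename_axis("sample").to_csv(
            labels_path, sep="\t"
        )


def read_genotypes(path, labels_path) -> GenotypeSet:
    dosages = pd.read_csv(path, sep="\t", index_col=0).T
    group = pd.read_csv(labels_path, sep="\t", index_col=0)["group"]
    return GenotypeSet(dosages, group)


def write_config_echo(params: dict, path) -> None:
    """Flat ``key = value`` echo of run parameters, round-trippable."""
    with open(path, "w") as fh:
        for key in sorted(params):
            fh.write(f"{key} = {params[key]!r}\n")


def read_config_echo(path) -> dict:
    import ast

    params = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        params[key.strip()] = ast.literal_eval(value.strip())
    return params
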