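"""On-disk formats: MTX + barcodes/features TSV per patient, plain TSV tables.

Stages of the pipeline communicate through these files so each is
independently runnable; matrices are stored cells x genes in MatrixMarket
format with sidecar ``barcodes.tsv`` and ``features.tsv``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from anndata import AnnData
from scipy import io as scio
from scipy import sparse


def write_patient_mtx(adata: AnnData, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scio.mmwrite(str(directory / "matrix.mtx"), sparse.coo_matrix(adata.X))
    adata.obs.reset_index().rename(columns={"index": "cell_id"}).to_csv(
        directory / "barcodes.tsv", sep="\t", index=False
    )
    adata.var.reset_index().rename(columns={"index": "gene"}).to_csv(
        directory / "features.tsv", sep="\t", index=False
    )


def read_patient_mtx(directory) -> AnnData:
    directory = Path(directory)
    X = sparse.csr_matrix(scio.mmread(str(directory / "matrix.mtx")))
    obs = pd.read_csv(directory / "barcodes.tsv", sep="\t")
    obs = obs.set_index(obs.columns[0])
    var = pd.read_csv(directory / "features.tsv", sep="\t")
    var = var.set_index(var.columns[0])
    return AnnData(X=X, obs=obs, var=var)


def write_gene_order(gene_order: pd.DataFrame, path) -> None:
    gene_order[["gene", "chromosome", "start"]].to_csv(path, sep="\t", index=False)


def read_gene_order(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chromosome", "start"}
    if not required <= set(df.columns):
        raise ValueError(f"gene order file must have columns {sorted(required)}")
    return df


def read_markers(path) -> dict[str, tuple[str, ...]]:
    """Marker sets from YAML (type -> list) or TSV (type, gene) files."""
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return {t: tuple(genes) for t, genes in raw.items()}
    df = pd.read_csv(path, sep="\t")
    return {
        t: tuple(sub["gene"]) for t, sub in df.groupby("type", sort=False)
    }


def read_lr_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"ligand", "receptor"} <= set(df.columns):
        raise ValueError("ligand-receptor file must have columns ligand, receptor")
    if "pair_id" not in df.columns:
        df["pair_id"] = df["ligand"] + "_" + df["receptor"]
    return df


def write_graph(graph, path) -> None:
    """Edge list TSV (node1, node2, weight)."""
    rows = [
        {"node1": a, "node2": b, "weight": d.get("weight", 1)}
        for a, b, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node1", "node2", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def write_ground_truth(truth, path) -> None:
    truth.cells.reset_index().to_csv(path, sep="\t", index=False)
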