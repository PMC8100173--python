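"""End-to-end orchestration: simulate -> qc -> celltype -> cna -> ith -> interactions.

Stages communicate through standard on-disk formats under a run
directory, every run writes a machine-readable JSON manifest, and any
stage failure aborts with the failing stage named while earlier outputs
are preserved.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from . import celltype as ct
from . import cna as cna_mod
from . import interactions as ia
from . import io as sio
from . import ith as ith_mod
from . import qc as qc_mod
from .simulate import SimulationConfig, generate_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:  # noqa: BLE001 - abort naming the stage
        raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    logger.info("stage %s: done", name)


@dataclass
class PipelineConfig:
    """One config object driving the whole pipeline.

    ``mode`` is "simulated" (the bundled cohort generator provides the
    inputs) or "user" (matrices + gene order are read from disk).
    """

    out_dir: str = "scith_run"
    seed: int = 0
    mode: str = "simulated"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    input_dir: str | None = None
    gene_order_path: str | None = None
    markers_path: str | None = None
    lr_path: str | None = None
    call_cells: bool = False
    qc_thresholds: qc_mod.QCThresholds = field(default_factory=qc_mod.QCThresholds)
    cna_params: cna_mod.CNAParams = field(default_factory=cna_mod.CNAParams)
    cna_clip: bool = True
    n_permutations: int = 1000
    alpha: float = 0.05
    max_rank: float = 0.1
    min_patients: int = 5
    min_interactions: int = 500
    interaction_network_scale: float = 1.0
    patient_groups: dict | None = None

    def validate(self) -> None:
        if self.mode not in {"simulated", "user"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "user":
            for label, path in [
                ("input_dir", self.input_dir),
                ("gene_order_path", self.gene_order_path),
            ]:
                if path is None:
                    raise ValueError(f"user mode requires {label}")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{label} does not exist: {path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw:
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        if "qc_thresholds" in raw:
            raw["qc_thresholds"] = qc_mod.QCThresholds(**raw["qc_thresholds"])
        if "cna_params" in raw:
            raw["cna_params"] = cna_mod.CNAParams(**raw["cna_params"])
        return cls(**raw)


def _load_user_cohort(config: PipelineConfig):
    root = Path(config.input_dir)
    patient_dirs = sorted(p for p in root.iterdir() if (p / "matrix.mtx").exists())
    if not patient_dirs:
        raise FileNotFoundError(f"no patient matrices under {root}")
    adatas = [sio.read_patient_mtx(p) for p in patient_dirs]
    for adata, p in zip(adatas, patient_dirs):
        if "patient" not in adata.obs:
            adata.obs["patient"] = p.name
    gene_order = sio.read_gene_order(config.gene_order_path)
    return adatas, None, gene_order


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a dict of the main result tables.

    Outputs land under ``config.out_dir``: per-patient matrices and QC
    tables, the CNA matrix, ITH/group-test/correlation tables, the
    retained interaction set, both networks as edge lists, a cohort
    table and ``manifest.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    survivor_counts: dict[str, int] = {}

    with _stage("input"):
        if config.mode == "simulated":
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            adatas, truth, gene_order = generate_cohort(sim)
            sio.write_ground_truth(truth, out / "ground_truth.tsv")
        else:
            adatas, truth, gene_order = _load_user_cohort(config)
        sio.write_gene_order(gene_order, out / "gene_order.tsv")
        for adata in adatas:
            sio.write_patient_mtx(adata, out / "raw" / adata.obs["patient"].iloc[0])

    with _stage("qc"):
        filtered = []
        for adata in adatas:
            patient = adata.obs["patient"].iloc[0]
            if config.call_cells:
                totals = np.asarray(adata.X.sum(axis=1)).ravel()
                adata = adata[qc_mod.call_cells_knee(totals)].copy()
            qc = qc_mod.compute_qc(adata)
            kept = qc_mod.filter_cells(adata, qc, config.qc_thresholds)
            qc["pass"] = qc.index.isin(kept.obs_names)
            qc.reset_index().to_csv(out / f"qc_{patient}.tsv", sep="\t", index=False)
            survivor_counts[patient] = kept.n_obs
            if kept.n_obs:
                filtered.append(kept)
        if not filtered:
            raise ValueError("no cells survived QC")
        cohort = ad.concat(filtered, merge="same")
        cohort.obs_names_make_unique()

    with _stage("normalize"):
        cohort = qc_mod.lognormalize(cohort)

    with _stage("celltype"):
        markers = sio.read_markers(config.markers_path) if config.markers_path else None
        if config.mode == "simulated":
            clusters = cohort.obs["cell_type"].to_numpy()
        elif "cluster" in cohort.obs:
            clusters = cohort.obs["cluster"].to_numpy()
        else:
            raise ValueError("user mode requires a 'cluster' column in barcodes")
        scores = ct.score_clusters(cohort, clusters, markers)
        cancer_clusters = ct.identify_cancer_clusters(scores, cohort, clusters)
        assigned = pd.Series(clusters).map(scores.winners).to_numpy()
        malignant = np.isin(clusters, list(cancer_clusters))
        cohort.obs["assigned_type"] = np.where(malignant, "Cancer", assigned)
        cohort.obs["malignant"] = malignant
        scores.scores.to_csv(out / "cluster_scores.tsv", sep="\t")
        subtype_calls = []
        for patient, sub in cohort.obs.groupby("patient", sort=True, observed=True):
            rows = sub.index[sub["malignant"]]
            if len(rows) == 0:
                warnings.warn(f"patient {patient}: no malignant cells; subtype skipped")
                continue
            subtype_calls.append(ct.subtype_scores(cohort[rows].copy(), str(patient)))
        subtypes = pd.DataFrame(
            [dataclasses.asdict(c) for c in subtype_calls],
            columns=["patient", "luad_score", "lusc_score", "label"],
        ).set_index("patient")
        subtypes.to_csv(out / "subtypes.tsv", sep="\t")

    with _stage("cna"):
        ordered = cna_mod.order_genes(cohort, gene_order)
        cna = cna_mod.infer_cna(
            ordered,
            cohort.obs["malignant"].to_numpy(),
            config.cna_params,
            clip=config.cna_clip,
        )
        viz = cna_mod.subsample_for_viz(cna, config.cna_params, seed=config.seed)
        pd.DataFrame(viz.X, index=viz.obs_names, columns=viz.var_names).to_csv(
            out / "cna_viz.tsv", sep="\t"
        )

    with _stage("ith"):
        results = []
        mal = cna.obs["malignant"].to_numpy()
        gex = cohort[:, cna.var_names].X
        for patient in pd.unique(cna.obs["patient"]):
            rows = np.flatnonzero((cna.obs["patient"].to_numpy() == patient) & mal)
            results.append(
                ith_mod.compute_ith(str(patient), cna.X[rows], gex[rows])
            )
        ith_table = ith_mod.results_table(results)
        ith_table.to_csv(out / "ith.tsv", sep="\t")

    with _stage("composition"):
        comp = (
            cohort.obs.groupby("patient", observed=True)["assigned_type"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
        )
        comp.to_csv(out / "composition.tsv", sep="\t")
        groups = pd.Series(config.patient_groups) if config.patient_groups else subtypes["label"]
        observed = sorted(pd.unique(groups.dropna()))
        pairs = tuple(combinations(observed, 2))
        group_tests = ith_mod.compare_groups(ith_table, groups, pairs=pairs) if pairs else pd.DataFrame()
        group_tests.to_csv(out / "group_tests.tsv", sep="\t", index=False)
        n_defined = int(ith_table["defined"].sum())
        if n_defined >= 4:
            corr = ith_mod.correlate_ith_composition(ith_table, comp)
            corr.to_csv(out / "composition_correlations.tsv", sep="\t")
        else:
            warnings.warn("fewer than 4 patients with defined ITH; correlations skipped")
            corr = pd.DataFrame()

    with _stage("interactions"):
        db = sio.read_lr_pairs(config.lr_path) if config.lr_path else None
        seeds = np.random.SeedSequence(config.seed).spawn(len(pd.unique(cohort.obs["patient"])))
        tests_by_patient = {}
        for ss, patient in zip(seeds, pd.unique(cohort.obs["patient"])):
            rows = cohort.obs["patient"].to_numpy() == patient
            sub = cohort[rows]
            tests = ia.permutation_test(
                sub,
                sub.obs["assigned_type"].to_numpy(),
                db=db,
                n_permutations=config.n_permutations,
                seed=int(ss.generate_state(1)[0] % (2**31)),
                alpha=config.alpha,
            )
            tests_by_patient[str(patient)] = ia.compute_rank(tests, alpha=config.alpha)
        retained = ia.aggregate_patients(
            tests_by_patient,
            min_patients=config.min_patients,
            alpha=config.alpha,
            max_rank=config.max_rank,
            groups=groups.to_dict(),
        )
        retained.to_csv(out / "retained_interactions.tsv", sep="\t", index=False)
        threshold = max(1, int(round(config.min_interactions * config.interaction_network_scale)))
        cell_net = ia.build_celltype_network(retained, min_interactions=threshold)
        sio.write_graph(cell_net, out / "celltype_network.tsv")
        type_expr = pd.DataFrame(
            {
                t: np.asarray(
                    cohort[cohort.obs["assigned_type"] == t].X.mean(axis=0)
                ).ravel()
                for t in pd.unique(cohort.obs["assigned_type"])
            },
            index=cohort.var_names,
        ).T
        components = ia.build_gene_network(retained, type_expr)
        comp_rows = [
            {"component": i, "gene": g}
            for i, sub in enumerate(components)
            for g in sorted(sub.nodes)
        ]
        pd.DataFrame(comp_rows, columns=["component", "gene"]).to_csv(
            out / "gene_network_components.tsv", sep="\t", index=False
        )

    with _stage("report"):
        cohort_table = ith_table.join(subtypes, how="left")
        cohort_table["group"] = groups.reindex(cohort_table.index)
        cohort_table = cohort_table.join(comp.add_prefix("prop_"), how="left")
        cohort_table.to_csv(out / "cohort_table.tsv", sep="\t")
        manifest = {
            "version": _version,
            "seed": config.seed,
            "mode": config.mode,
            "qc_thresholds": dataclasses.asdict(config.qc_thresholds),
            "cna_params": dataclasses.asdict(config.cna_params),
            "n_permutations": config.n_permutations,
            "alpha": config.alpha,
            "max_rank": config.max_rank,
            "min_patients": config.min_patients,
            "survivor_counts": survivor_counts,
            "n_cells_final": int(cohort.n_obs),
            "n_retained_interactions": int(len(retained)),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "cohort_table": cohort_table,
        "ith": ith_table,
        "group_tests": group_tests,
        "composition": comp,
        "composition_correlations": corr,
        "retained_interactions": retained,
        "celltype_network": cell_net,
        "gene_network_components": components,
        "manifest": manifest,
    }
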