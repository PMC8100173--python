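"""Synthetic multi-patient scRNA-seq cohorts with known ground truth.

Counts are drawn from a negative-binomial model in which copy-number
segments act multiplicatively on malignant-cell gene means, cell-type
marker programs upregulate their marker genes, and ligand-receptor
signals upregulate a ligand in a sender type and a receptor in a
receiver type.  Every downstream stage of the package (QC, CNA
inference, heterogeneity scoring, cell typing, interaction testing) can
therefore be validated against planted truth without any external data.

Randomness derives from a single integer seed through
``numpy.random.SeedSequence``: child sequences are spawned in a fixed
order (gene universe first, then one per patient), so cohorts are
bit-reproducible and individual patients are independent streams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

logger = logging.getLogger(__name__)

# Marker panels used by the subtype classifier; planted in malignant
# cells when the simulated patient carries the corresponding subtype.
LUAD_MARKERS = ("NAPSA", "NKX2-1")
LUSC_MARKERS = ("KRT5", "DSG3", "TP63")


@dataclass(frozen=True)
class CNASegment:
    """A contiguous copy-number segment carried by one clone.

    ``start`` and ``length`` are 0-based gene indices within
    ``chromosome``; ``fold`` multiplies the NB mean of every gene in the
    segment for malignant cells of clone ``clone``.
    """

    chromosome: str
    start: int
    length: int
    fold: float
    clone: int = 0

    @property
    def stop(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class LRSignal:
    """Planted ligand-receptor co-expression between two cell types."""

    ligand: str
    receptor: str
    sender: str
    receiver: str
    effect: float = 10.0


@dataclass(frozen=True)
class CellTypeProfile:
    markers: tuple[str, ...] = ()
    marker_effect: float = 8.0
    malignant: bool = False


def default_profiles() -> dict[str, CellTypeProfile]:
    """Marker programs mirroring the major cell types of an NSCLC biopsy."""
    return {
        # carcinoma cells express EPCAM strongly and near-uniformly
        "Cancer": CellTypeProfile(markers=("EPCAM",), marker_effect=20.0, malignant=True),
        "T": CellTypeProfile(markers=("CD2", "CD3D", "CD3E", "CD3G")),
        "Myeloid": CellTypeProfile(markers=("CD14", "LYZ")),
        "Neutrophil": CellTypeProfile(markers=("CSF3R", "S100A8", "S100A9")),
        "Fibroblast": CellTypeProfile(markers=("COL1A1", "COL1A2", "DCN")),
        "Endothelial": CellTypeProfile(markers=("CLDN5", "VWF", "PECAM1")),
    }


def _default_cells() -> dict[str, int]:
    return {
        "Cancer": 200,
        "T": 100,
        "Myeloid": 80,
        "Neutrophil": 40,
        "Fibroblast": 60,
        "Endothelial": 40,
    }


def _default_chromosomes() -> dict[str, int]:
    return {f"chr{i}": 220 for i in range(1, 6)}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Parameters
    ----------
    genes_per_chromosome
        Number of (generic) genes on each autosome; genomic order within
        a chromosome follows construction order.
    cell_type_profiles
        Per-type marker genes and effect multipliers; exactly the types
        listed in ``n_cells_per_type`` are emitted.
    clones_per_patient / patient_clones
        Number of malignant clones, globally or per patient.  Clone k of
        every patient carries the segments whose ``clone`` field is k.
    nb_dispersion
        Negative-binomial size parameter theta (variance mu + mu^2/theta).
    lr_signals
        Ligand-receptor signals baked into the generative means.
    patient_subtypes
        Optional "LUAD"/"LUSC" label per patient; the corresponding
        marker panel is upregulated in that patient's malignant cells.
    marker_baseline_mean
        Baseline NB mean (counts per cell at the median library size)
        given to every planted named gene, making marker and
        ligand-receptor programs cell-type specific the way canonical
        markers are; ``None`` leaves the log-normal baseline draw.
        ``gene_baseline_overrides`` overrides single genes by name.
    n_empty_droplets
        Low-count barcodes appended per patient so knee-based cell
        calling has a rank curve to cut.
    """

    n_patients: int = 12
    genes_per_chromosome: Mapping[str, int] = field(default_factory=_default_chromosomes)
    cell_type_profiles: Mapping[str, CellTypeProfile] = field(default_factory=default_profiles)
    n_cells_per_type: Mapping[str, int] = field(default_factory=_default_cells)
    clones_per_patient: int = 1
    patient_clones: Sequence[int] | None = None
    cna_segments: Sequence[CNASegment] = ()
    nb_dispersion: float = 2.0
    lib_size_median: float = 3000.0
    lib_size_sigma: float = 0.4
    mito_gene_count: int = 10
    mito_mass_fraction: float = 0.08
    high_mito_fraction: float = 0.0
    high_mito_scale: float = 8.0
    lr_signals: Sequence[LRSignal] = field(
        default_factory=lambda: (
            LRSignal("CXCL1", "CXCR2", "Cancer", "Neutrophil"),
            LRSignal("VEGFA", "KDR", "Cancer", "Endothelial"),
            LRSignal("CD274", "PDCD1", "Myeloid", "T"),
        )
    )
    patient_subtypes: Sequence[str] | None = None
    subtype_marker_effect: float = 8.0
    marker_baseline_mean: float | None = 0.05
    gene_baseline_overrides: Mapping[str, float] = field(default_factory=dict)
    n_empty_droplets: int = 0
    empty_umi_mean: float = 20.0
    seed: int = 0

    def clone_count(self, patient_index: int) -> int:
        if self.patient_clones is not None:
            return int(self.patient_clones[patient_index])
        return self.clones_per_patient

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for chrom, n in self.genes_per_chromosome.items():
            if n < 1:
                raise ValueError(f"chromosome {chrom!r} must have >= 1 gene")
        if any(n < 0 for n in self.n_cells_per_type.values()):
            raise ValueError("cell counts must be >= 0")
        if sum(self.n_cells_per_type.values()) == 0:
            raise ValueError("zero-cell patients are not allowed")
        unknown = set(self.n_cells_per_type) - set(self.cell_type_profiles)
        if unknown:
            raise ValueError(f"cell types without profiles: {sorted(unknown)}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0 <= self.mito_mass_fraction < 1:
            raise ValueError("mito_mass_fraction must lie in [0, 1)")
        if not 0 <= self.high_mito_fraction <= 1:
            raise ValueError("high_mito_fraction must lie in [0, 1]")
        if self.patient_clones is not None and len(self.patient_clones) != self.n_patients:
            raise ValueError("patient_clones must have one entry per patient")
        if self.patient_subtypes is not None:
            if len(self.patient_subtypes) != self.n_patients:
                raise ValueError("patient_subtypes must have one entry per patient")
            bad = set(self.patient_subtypes) - {"LUAD", "LUSC"}
            if bad:
                raise ValueError(f"unknown subtypes: {sorted(bad)}")
        max_clones = max(
            (self.clone_count(p) for p in range(self.n_patients)), default=0
        )
        by_clone_chrom: dict[tuple[int, str], list[CNASegment]] = {}
        for seg in self.cna_segments:
            if seg.fold <= 0:
                raise ValueError(f"segment fold must be > 0, got {seg.fold}")
            if seg.length < 1:
                raise ValueError("segment length must be >= 1")
            if seg.chromosome not in self.genes_per_chromosome:
                raise ValueError(f"segment on unknown chromosome {seg.chromosome!r}")
            size = self.genes_per_chromosome[seg.chromosome]
            if seg.start < 0 or seg.stop > size:
                raise ValueError(
                    f"segment {seg.chromosome}:{seg.start}-{seg.stop} exceeds "
                    f"chromosome size {size}"
                )
            if seg.clone < 0 or seg.clone >= max_clones:
                raise ValueError(
                    f"segment assigned to clone {seg.clone} but at most "
                    f"{max_clones} clones are configured"
                )
            by_clone_chrom.setdefault((seg.clone, seg.chromosome), []).append(seg)
        for (clone, chrom), segs in by_clone_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start < a.stop:
                    raise ValueError(
                        f"overlapping segments within clone {clone} on {chrom}: "
                        f"{a.start}-{a.stop} and {b.start}-{b.stop}"
                    )
        for sig in self.lr_signals:
            if sig.effect <= 0:
                raise ValueError("lr signal effect must be > 0")
            for t in (sig.sender, sig.receiver):
                if t not in self.cell_type_profiles:
                    raise ValueError(f"lr signal names unknown cell type {t!r}")
        if self.marker_baseline_mean is not None and self.marker_baseline_mean <= 0:
            raise ValueError("marker_baseline_mean must be > 0")
        if any(m <= 0 for m in self.gene_baseline_overrides.values()):
            raise ValueError("gene baseline overrides must be > 0")
        n_special = len(self._special_genes())
        n_auto = sum(self.genes_per_chromosome.values())
        if n_special > n_auto:
            raise ValueError("more named genes than positions in the gene universe")

    def _special_genes(self) -> list[str]:
        """Named genes to plant into the universe, deduplicated in order."""
        names: list[str] = []
        for prof in self.cell_type_profiles.values():
            names.extend(prof.markers)
        if self.patient_subtypes is not None:
            names.extend(LUAD_MARKERS)
            names.extend(LUSC_MARKERS)
        for sig in self.lr_signals:
            names.extend((sig.ligand, sig.receptor))
        seen: set[str] = set()
        out = []
        for n in names:
            if n not in seen:
                seen.add(n)
                out.append(n)
        return out


@dataclass
class GroundTruth:
    """Planted truth for one cohort.

    ``cells`` has one row per real cell (cell_id, patient, cell_type,
    clone, malignant); ``clone_profiles`` is genes x clones of true
    per-gene fold changes; ``patient_subtypes`` maps patient id to the
    planted histological subtype (empty when none was planted).
    """

    cells: pd.DataFrame
    clone_profiles: pd.DataFrame
    patient_subtypes: pd.Series

    def n_malignant(self) -> int:
        return int(self.cells["malignant"].sum())


def _build_universe(config: SimulationConfig, ss: np.random.SeedSequence):
    """Gene order, per-gene baseline weights and per-clone fold vectors."""
    rng = np.random.default_rng(ss)
    chroms: list[str] = []
    names: list[str] = []
    starts: list[int] = []
    offsets: dict[str, int] = {}
    pos = 0
    for chrom, n in config.genes_per_chromosome.items():
        offsets[chrom] = pos
        for i in range(n):
            names.append(f"{chrom}-G{i + 1:04d}")
            chroms.append(chrom)
            starts.append((i + 1) * 10_000)
        pos += n
    n_auto = pos
    for i in range(config.mito_gene_count):
        names.append(f"MT-G{i + 1}")
        chroms.append("MT")
        starts.append((i + 1) * 1_000)

    special = config._special_genes()
    if special:
        slots = np.sort(rng.choice(n_auto, size=len(special), replace=False))
        for slot, name in zip(slots, special):
            names[slot] = name

    gene_order = pd.DataFrame(
        {"gene": names, "chromosome": chroms, "start": starts}
    )
    if gene_order["gene"].duplicated().any():
        raise ValueError("duplicate gene names in universe")

    n_genes = len(names)
    weights = np.zeros(n_genes)
    weights[:n_auto] = rng.lognormal(mean=0.0, sigma=1.0, size=n_auto)

    # pin the baseline NB mean (at the median library size) of planted
    # genes: weight w solves mean = lib_median * w / sum(weights)
    targets: dict[str, float] = {}
    if config.marker_baseline_mean is not None:
        targets.update({g: config.marker_baseline_mean for g in special})
    targets.update(config.gene_baseline_overrides)
    if targets:
        name_pos = {n: i for i, n in enumerate(names[:n_auto])}
        unknown = [g for g in targets if g not in name_pos]
        if unknown:
            raise ValueError(f"baseline override for unknown genes: {unknown}")
        cols = np.array([name_pos[g] for g in targets])
        ratios = np.array([m / config.lib_size_median for m in targets.values()])
        others = np.delete(weights[:n_auto], cols).sum()
        total = others / (1.0 - ratios.sum())
        weights[cols] = ratios * total

    if config.mito_gene_count and config.mito_mass_fraction > 0:
        mito_mass = (
            config.mito_mass_fraction
            / (1 - config.mito_mass_fraction)
            * weights[:n_auto].sum()
        )
        weights[n_auto:] = mito_mass / config.mito_gene_count

    max_clones = max(
        (config.clone_count(p) for p in range(config.n_patients)), default=1
    )
    folds = np.ones((max(max_clones, 1), n_genes))
    for seg in config.cna_segments:
        lo = offsets[seg.chromosome] + seg.start
        folds[seg.clone, lo : lo + seg.length] *= seg.fold
    return gene_order, weights, folds, n_auto


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """NB(mean, size=theta) draws; mean 0 yields 0 exactly."""
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p).astype(np.int32)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[AnnData], GroundTruth, pd.DataFrame]:
    """Simulate one cohort.

    Returns
    -------
    adatas
        One AnnData per patient (cells x genes sparse UMI counts,
        ``obs``: patient, cell_type, clone, malignant, is_cell).
    truth
        :class:`GroundTruth` for all real cells.
    gene_order
        (gene, chromosome, start) in genomic order, mitochondrial
        pseudo-chromosome last.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_universe, *ss_patients = root.spawn(config.n_patients + 1)
    gene_order, weights, folds, _ = _build_universe(config, ss_universe)
    n_genes = len(gene_order)
    gene_idx = pd.Index(gene_order["gene"])
    wsum = weights.sum()

    marker_cols = {
        t: gene_idx.get_indexer(p.markers)
        for t, p in config.cell_type_profiles.items()
    }
    luad_cols = gene_idx.get_indexer(LUAD_MARKERS)
    lusc_cols = gene_idx.get_indexer(LUSC_MARKERS)
    mito_cols = np.flatnonzero(gene_order["chromosome"].to_numpy() == "MT")

    adatas: list[AnnData] = []
    truth_rows: list[pd.DataFrame] = []
    subtype_map: dict[str, str] = {}

    for p in range(config.n_patients):
        rng = np.random.default_rng(ss_patients[p])
        patient = f"P{p + 1:02d}"
        types: list[str] = []
        for t, n in config.n_cells_per_type.items():
            types.extend([t] * n)
        n_cells = len(types)
        type_arr = np.array(types)
        malignant = np.array(
            [config.cell_type_profiles[t].malignant for t in types]
        )

        k = config.clone_count(p)
        clone = np.full(n_cells, -1)
        n_mal = int(malignant.sum())
        if n_mal and k > 0:
            clone[malignant] = rng.integers(0, k, size=n_mal)

        lib = rng.lognormal(np.log(config.lib_size_median), config.lib_size_sigma, n_cells)

        mult = np.ones((n_cells, n_genes))
        for t, prof in config.cell_type_profiles.items():
            cols = marker_cols[t]
            cols = cols[cols >= 0]
            if len(cols) == 0:
                continue
            rows = type_arr == t
            if rows.any():
                mult[np.ix_(rows, cols)] *= prof.marker_effect
        if config.patient_subtypes is not None:
            subtype = config.patient_subtypes[p]
            subtype_map[patient] = subtype
            cols = luad_cols if subtype == "LUAD" else lusc_cols
            if malignant.any():
                mult[np.ix_(malignant, cols)] *= config.subtype_marker_effect
        if malignant.any():
            mult[malignant] *= folds[clone[malignant]]
        for sig in config.lr_signals:
            li = gene_idx.get_loc(sig.ligand)
            ri = gene_idx.get_loc(sig.receptor)
            mult[type_arr == sig.sender, li] *= sig.effect
            mult[type_arr == sig.receiver, ri] *= sig.effect
        if config.high_mito_fraction > 0 and len(mito_cols):
            n_high = int(round(config.high_mito_fraction * n_cells))
            if n_high:
                high = rng.choice(n_cells, size=n_high, replace=False)
                mult[np.ix_(high, mito_cols)] *= config.high_mito_scale

        mean = lib[:, None] * (weights[None, :] * mult) / wsum
        counts = _nb_sample(rng, mean, config.nb_dispersion)

        is_cell = np.ones(n_cells, bool)
        if config.n_empty_droplets:
            empty_lib = rng.lognormal(
                np.log(config.empty_umi_mean), 0.5, config.n_empty_droplets
            )
            empty_mean = empty_lib[:, None] * weights[None, :] / wsum
            empty = _nb_sample(rng, empty_mean, config.nb_dispersion)
            counts = np.vstack([counts, empty])
            type_arr = np.concatenate([type_arr, [""] * config.n_empty_droplets])
            malignant = np.concatenate(
                [malignant, np.zeros(config.n_empty_droplets, bool)]
            )
            clone = np.concatenate([clone, np.full(config.n_empty_droplets, -1)])
            is_cell = np.concatenate([is_cell, np.zeros(config.n_empty_droplets, bool)])

        n_total = counts.shape[0]
        cell_ids = [f"{patient}_C{i + 1:05d}" for i in range(n_total)]
        obs = pd.DataFrame(
            {
                "patient": patient,
                "cell_type": type_arr,
                "clone": ["" if c < 0 else f"clone{c}" for c in clone],
                "malignant": malignant,
                "is_cell": is_cell,
            },
            index=pd.Index(cell_ids, name="cell_id"),
        )
        var = gene_order.set_index("gene")[["chromosome", "start"]].copy()
        adata = AnnData(X=sparse.csr_matrix(counts), obs=obs, var=var)
        adatas.append(adata)
        truth_rows.append(obs.loc[is_cell, ["patient", "cell_type", "clone", "malignant"]])

    clone_profiles = pd.DataFrame(
        folds.T,
        index=gene_idx,
        columns=[f"clone{i}" for i in range(folds.shape[0])],
    )
    truth = GroundTruth(
        cells=pd.concat(truth_rows),
        clone_profiles=clone_profiles,
        patient_subtypes=pd.Series(subtype_map, dtype=object),
    )
    return adatas, truth, gene_order


def plant_lr_signal(adata: AnnData, signal: LRSignal) -> AnnData:
    """Scale a ligand in sender cells and a receptor in receiver cells.

    Deterministic post-hoc planting: entries of the ligand gene in
    sender-type cells (and receptor gene in receiver-type cells) are
    multiplied by ``signal.effect``; every other entry is untouched.
    """
    for gene in (signal.ligand, signal.receptor):
        if gene not in adata.var_names:
            raise KeyError(f"unknown gene {gene!r}")
    present = set(adata.obs["cell_type"])
    for t in (signal.sender, signal.receiver):
        if t not in present:
            raise KeyError(f"unknown cell type {t!r}")
    out = adata.copy()
    X = sparse.lil_matrix(out.X)
    for gene, ctype in ((signal.ligand, signal.sender), (signal.receptor, signal.receiver)):
        col = out.var_names.get_loc(gene)
        rows = np.flatnonzero((out.obs["cell_type"] == ctype).to_numpy())
        X[rows, col] = X[rows, col].toarray() * signal.effect
    out.X = X.tocsr()
    return out


def neutral_config(**overrides) -> SimulationConfig:
    """A copy-neutral, marker-free baseline config (all NB means shared)."""
    profiles = {
        "Cancer": CellTypeProfile(markers=(), malignant=True),
        "Stromal": CellTypeProfile(markers=()),
    }
    cfg = SimulationConfig(
        n_patients=1,
        cell_type_profiles=profiles,
        n_cells_per_type={"Cancer": 200, "Stromal": 200},
        cna_segments=(),
        lr_signals=(),
    )
    return replace(cfg, **overrides)
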