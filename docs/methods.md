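# Methods

`scith` re-implements, as a tested library, the quantitative core of a
single-cell analysis of advanced non-small cell lung cancer (NSCLC)
biopsies: barcode knee calling and cell-level quality control,
expression-inferred relative copy-number (CNA) profiles, intratumor
heterogeneity (ITH) scores, marker-score cell typing with LUAD/LUSC
patient classification, and permutation-tested ligand–receptor
interaction networks. A synthetic cohort generator with planted ground
truth makes every stage testable without external data. This note
records the models, the parameters that matter, and the design choices
made where the procedure left them open.

## Synthetic cohorts (`scith.simulate`)

Counts are negative binomial: cell *c*, gene *g* has mean
μ_cg = L_c · w_g · m_cg / Σ w and variance μ + μ²/θ, with

- w_g — per-gene baseline weight, LogNormal(0, 1); genes planted by
  name (markers, subtype panels, ligand–receptor partners) instead get
  a pinned baseline mean (`marker_baseline_mean`, default 0.05 counts
  per cell at the median library size) so that, as for real canonical
  markers and receptors, baseline expression is rare and type-specific
  upregulation is informative;
- L_c — library size, LogNormal(ln median, σ) with median 3000 and
  σ = 0.4, so QC thresholds bite realistically;
- m_cg — a product of multipliers: the cell type's marker effect
  (default 8; 20 for EPCAM in malignant cells, which express it
  near-uniformly), the patient's planted LUAD/LUSC subtype panel in
  malignant cells, the clone's copy-number fold at g (gains/losses act
  multiplicatively on the mean, the dosage assumption underlying
  expression-based CNA inference), and any planted ligand–receptor
  effect (ligand × effect in sender cells, receptor × effect in
  receiver cells);
- θ — NB size (`nb_dispersion`, default 2), a typical UMI-level
  overdispersion.

Mitochondrial genes form a pseudo-chromosome "MT" holding a configured
fraction (8%) of baseline transcript mass; a configurable fraction of
cells has that mass scaled ×8 to exceed the 30% QC cutoff. Optional
empty droplets (low library, same gene weights) give the knee caller a
rank curve to cut. Clones partition a patient's malignant cells
uniformly; segments of the same clone may not overlap. All randomness
derives from one integer seed via `numpy.random.SeedSequence` spawned
in a fixed order (gene universe, then one stream per patient), so
cohorts are byte-reproducible.

What the generator does **not** emulate: doublets, ambient RNA
contamination, batch effects, gene–gene co-expression structure beyond
the planted programs, and read-level noise. Passing tests therefore
demonstrate correctness of the computations and recoverability of
planted signals under an idealized NB model — not robustness to every
artifact of real libraries.

## Cell calling and QC (`scith.qc`)

Knee calling sorts positive barcode totals descending and, on the
log10(rank)–log10(total) curve, takes the point with maximal
perpendicular distance to the chord joining the curve's endpoints
(ties toward higher totals); all barcodes with totals ≥ the knee
barcode's total are retained. A flat curve retains everything; fewer
than 10 positive barcodes is an error.

Cell filters use a strict reading of their bounds: cells are removed
when expressed genes < 200 or > 5000, total UMIs > 30,000, or
mitochondrial fraction (UMIs in genes matching `^MT-`,
case-insensitive) > 30% — so a cell sitting exactly on a bound
survives. The mitochondrial fraction of an all-zero cell is defined as
0 (the gene filter removes it regardless). Normalization is
ln(1 + count·10⁴/cell total), the conventional behavior of the cited
normalization step, with all-zero cells left at zero.

## CNA inference (`scith.cna`)

Genes are ordered by chromosome (1–22, X, Y, then others) and start
coordinate. Genes expressed in fewer than 20 cells are dropped.
Relative expression is the log-normalized value minus the per-gene mean
over reference cells — all cells not flagged malignant, pooled
cohort-wide by the pipeline (per-patient references are available via
flag). Each value is then replaced by the mean of a 101-gene window
centered on it within its chromosome; windows truncate at chromosome
ends (never mirror, never span boundaries), keeping the gene axis
aligned across cells.

"Centering to 1" is implemented as per-cell **median** subtraction plus
1; the median is robust when true CNAs occupy part of the genome, and
the centering statistic was otherwise unspecified. Clipping bounds are
1 ± 1.5σ where σ is the standard deviation of the whole centered
matrix (computed once; zero variance skips clipping). Clipped values
feed both the heatmap subsampling (at most 100 malignant cells per
patient, sampled without replacement, seeded) and ITH_CNA; an unclipped
path exists for sensitivity analysis because the published pipeline is
ambiguous on whether clipping preceded the heterogeneity score.

## Heterogeneity scores (`scith.ith`)

For one patient, all C(n,2) Pearson correlation coefficients among
malignant-cell profiles are computed (constant profiles are excluded
with a warning; fewer than 3 cells makes the score undefined). The ITH
score is the interquartile range Q3 − Q1 of that distribution, using
linear interpolation between order statistics — the common quantile
default; the source defined no rule. ITH_CNA uses the relative CNA
matrix; ITH_GEX uses log-normalized expression over all genes surviving
the prevalence filter (no variable-gene selection, since the underlying
definition restricts to "gene expression profiles" without one).
Scores lie in [0, 2] and are invariant to per-cell affine transforms.

Group comparisons use the two-sided unpaired Wilcoxon rank-sum test:
exact null for combined n ≤ 25 without ties, normal approximation with
tie correction otherwise. Compositions (per-patient cell-type
proportions, validated to sum to 1 ± 10⁻⁶) are correlated with ITH by
Pearson's r with the two-sided t-test on n − 2 degrees of freedom;
fewer than 4 patients is an error.

## Cell typing and subtype calls (`scith.celltype`)

score(cluster, type) = mean over the type's marker genes of the
z-scored (across all cells) expression averaged over the cluster's
cells; z-scoring operationalizes "normalized expressions", which was
not given as a formula. Winners are argmax with ties broken by
definition order (warned). Clustering itself is an input — ground-truth
labels in simulation, any external clustering otherwise.

Cancer clusters are those with ≥ 30% EPCAM-positive (count > 0) cells
whose Epithelial and Alveolar marker scores are below z = 0.5; the
qualitative rule ("EPCAM-positive, negative for normal lung epithelial
markers") came without thresholds, so both are configurable. Two
marker-name ambiguities are resolved as FOLR1 (folate receptor,
alveolar) and DSG3 (squamous desmoglein), both configurable.

Patient subtype scores are the mean fraction of malignant cells
expressing each panel — LUAD: NAPSA, NKX2-1 (TTF-1); LUSC: KRT5, DSG3,
TP63. Both scores < 0.05 (under 5% of cells expressing the markers)
yields the residual label NSCLC; otherwise the higher score wins, ties
going to the first panel with a warning.

## Ligand–receptor interactions (`scith.interactions`)

For each (pair, sender, receiver): statistic = ½(mean ligand expression
in sender + mean receptor expression in receiver) on log-normalized
data. The null permutes cell-type labels across cells N = 1000 times;
p = (1 + #{null ≥ observed}) / (N + 1), so p ∈ [1/(N+1), 1]. Pairs
whose ligand or receptor is expressed in < 10% of the respective type
are non-specific by construction and get p = 1. Statistic, floor and
pseudocount follow the cited tool's documented default behavior;
heteromeric complexes are out of scope (simple pairs only).

Per patient, a pair's specificity rank is the fraction of type-pairs in
which it is significant at α = 0.05 (α itself was unstated;
configurable); pairs with rank > 0.1 are discarded. The rank filter is
applied per patient **before** cross-patient aggregation — the ordering
was unstated and this order maximizes specificity. A triple is kept at
cohort level when it passes in strictly more than five patients
("more than five"), with per-group patient fractions annotated.

The cell-type network is undirected with edge weight = number of
retained interactions between the two types (directions summed); types
with fewer than 500 total retained interactions are dropped — a
cohort-scale default exposed as `min_interactions` with a scale factor
for small synthetic cohorts. The gene-only network removes cell-type
nodes from a master graph (type→gene expression edges above a mean
floor, gene–gene edges for retained pairs) and reports the four largest
connected components by node count, ties by edge count then smallest
member. A bundled ~46-pair database (CXCL/CCL chemokines, VEGF/PDGF/FGF
growth factors, TIGIT/CD226/CD96–PVR and CD274/CTLA4 checkpoints, and
others) serves tests and demos; real analyses should supply a full
database TSV.

## Pipeline (`scith.pipeline`)

Stages run simulate → QC → normalize → celltype → CNA → ITH →
composition → interactions → report, communicating through MTX/TSV
files under a run directory with a JSON manifest (parameters, seed,
survivor counts; no timestamps, so reruns are byte-identical). Any
stage failure aborts naming the stage; earlier outputs remain on disk.
In user-supplied mode all referenced files are checked before any
computation.

## Validation experiments (`scith.validation`)

Problem sizes chosen for the reproduction experiments (also run by
`scripts/acceptance.py`):

- **ITH directionality** — 50 replicate cohorts of 16 two-clone
  patients (clone 0: 150-gene fold-2 gain on chr1; clone 1: 150-gene
  fold-0.5 loss on chr2) vs 12 one-clone patients, 300 malignant + 150
  reference cells each; per replicate the group medians and the
  two-sided rank-sum p-value.
- **CNA recovery** — one 150-gene fold-2 gain, 500 + 500 cells;
  inside-vs-outside AUROC of per-gene malignant means via the rank-sum
  identity AUC = U/(n₁n₂).
- **CNA null** — copy-neutral 200 + 200 cells, 20 seeds; two-sample KS
  between malignant and reference smoothed values. Values within a
  cell are strongly window-correlated, so 2000 values per group are
  subsampled (seeded) before the test to keep its nominal sample size
  honest.
- **Interaction calibration** — 4 types × 250 cells with no signal, 80
  pairs drawn from well-expressed genes (so the 10% floor never
  triggers and every test exercises the permutation null), N = 1000,
  10 seeds: pooled type-I error at α = 0.05. Planted recovery: a
  lowly-expressed ligand/receptor pair upregulated ×10 in sender A /
  receiver B, 20 seeds; recovery = p at the 1/(N+1) floor with rank
  ≤ 0.1 (the low baseline is what keeps off-target triples below the
  expression floor, exactly the specificity the floor exists for).
- **Subtype recovery** — 8 patients × 20 seeds, subtype panels planted
  at effect 5 (the weakest effect the classifier is claimed to resolve)
  in 100 malignant cells.
- **Filter/network chain** — 100 random cohorts of structured test
  tables checked triple-for-triple against an independent nested-loop +
  union-find enumeration.

## Known limitations

- The CNA profile is relative expression, not copy number: strong
  transcriptional programs in malignant cells (here, planted markers)
  shift windows irrespective of dosage. No HMM state calling, subclone
  trees or allele-specific inference.
- ITH scores on no-CNA data are not 0; smoothing noise sets a floor
  (IQR of near-zero-mean correlations), so scores are comparative, not
  absolute.
- The permutation test inherits its statistic's known promiscuity: a
  strong sender-side signal can reach significance in off-target
  receiver types whenever the receptor clears the 10% floor; the rank
  filter, not the p-value, provides specificity.
- Boundary semantics of the QC filters (cells at exactly 200/5000
  genes, 30,000 UMIs, 30% mito survive) follow the strict wording of
  the procedure; the original cohort's handling of exact boundary
  values is unknown.
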