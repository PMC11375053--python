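# Methods

This note documents the models implemented in `tlsniche`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that make results reproducible.

## Expression scoring

**QC filter.** Units (cells or spots) are kept when total UMIs ≥ 1001,
detected genes ≥ 501 and mitochondrial UMI fraction ≤ 0.25; the boundary
values themselves are kept ("fewer than 1001" / "over 25 %" are removed).
Mitochondrial genes are matched by name prefix (default `MT-`), since no
fixed list generalises across annotations.

**Log-normalisation.** `value = ln(1 + count · s / total)` with scale
`s = 10 000`, delegated to scanpy (`normalize_total` + `log1p`). Zero-count
units stay zero and are reported, not dropped: the caller decides.

**Control-bin module score.** Genes are ranked by dataset-average
expression and cut into `n_bins = 24` equal-size bins; each signature gene
draws `n_ctrl = 100` control genes from its bin (signature genes excluded,
sampled without replacement); the unit's score is the mean of the signature
genes minus the mean of the pooled controls. The 24/100 defaults follow the
common single-cell implementation of this scheme. Two boundary rules are
ours: when a bin has fewer than `n_ctrl` candidates the draw falls back to
sampling with replacement (with a warning), and when signature genes exhaust
a bin entirely the control pool widens to adjacent bins until non-empty —
the nearest expression-matched background available. Scores are seeded and
deterministic; unit order is irrelevant.

**ssGSEA.** Per sample, genes are ranked by expression (average ranks on
ties; the descending ordering breaks residual ties by gene position, which
makes the score reproducible and permutation-invariant). The enrichment
score is the running sum of the weighted in-set ECDF (weights `rank^α`,
`α = 0.25`) minus the uniform out-of-set ECDF. Optional min–max rescaling
across samples is off by default because it changes only affine position,
not ordering; both modes are exposed since downstream correlation analyses
may want either.

**Marker ranking.** One-vs-rest two-sided Wilcoxon rank-sum per gene
(normal approximation with tie correction), Bonferroni adjustment over
genes (Benjamini–Hochberg available but not the default), retained when
adjusted p < 0.05 and log2 fold-change ≥ 0.25. Fold-change is the
difference of mean log-normalised expression divided by ln 2 — monotone,
simple and stable for the boundary tests; clusters with fewer than 3 units
are skipped. `top_k_signature` takes the top 100 genes per cluster in the
table's fold-change order.

**EBV DNA load.** Livak 2^−ΔΔCt against a positive-control calibrator;
samples split at the arithmetic cohort mean of the relative values. "Mean
fold of difference" is ambiguous between arithmetic and geometric means; the
arithmetic mean is used and documented here as the package's reading.

## Spatial compartments

**Geometries.** Visium-like hexagonal grids use offset rows at 100 µm
pitch; Stereo-seq raw spots (0.5 µm pitch) are aggregated by `bin100`
windows of 100 × 100 spots ≈ 49.72 µm, summing counts, with partial edge
windows kept and flagged.

**Region calling.** Malignant, B and T signature scores are z-standardised
across spots. A spot is TCA when the malignant z exceeds the threshold
(default 0.5) and is the maximum (ties included); TLS when the best
lymphocyte z exceeds the threshold and strictly beats the malignant z;
otherwise stroma. The 0.5 default is a compromise between sensitivity and
the false-TLS rate on noisy stroma; the original analysis additionally used
pathologist morphology, which has no computational counterpart here, so the
threshold is exposed in the API.

**TCA components.** Spots within `1.2 × pitch` are adjacent — giving the
natural 6-connectivity on hexagonal and 4-connectivity on square grids —
and connected components are labelled deterministically by smallest spot
id, so the partition is invariant to spot order.

**EBV stratification.** Quartiles of the EBV signature over all TCA spots
of a sample; strictly above Q3 → high, strictly below Q1 → low, else mid
(strict inequalities as the class definitions state). Components take the
majority vote of their spots, ties resolving to mid; fewer than 4 TCA spots
degenerate to all-mid with a warning. Spot-level quartiles plus a
component-level vote is the simplest lift from the spot-wise definition to
the per-aggregate classes reported downstream.

**Plasma co-occurrence.** A component is wP when at least one of its spots,
or any spot within one pitch of it (the halo capturing plasma cells at the
tumour margin), has a plasma-signature score strictly above the sample's
0.75 quantile. "With plasma cells" is nowhere quantified in the source
analysis; the any-hot-spot rule with an exposed quantile is this package's
operationalisation.

**Apoptosis comparison.** Welch's unequal-variance t-test for each class
pair (a robust default for "two-sided t-tests" on unequal group sizes),
with per-class n/mean/median/IQR and the name of the top-ranked class.

**Auxiliary statistics.** Normalised interaction = connection value divided
by the product of the two cluster sizes. Immune-infiltration bins 1–4 cover
(0, 25], (25, 50], (50, 75], (75, 100] % of infiltrated tumour area, with
0 % mapping to bin 1.

## Proximity statistics

Within-radius counts use a KD-tree but are exact; the boundary is closed
(a target at exactly 20 µm counts, reading "within 20 µm" inclusively).
Distance histograms are right-closed with the first bin including its left
edge, so counts conserve the number of targets. The CSR expectation
`E = n_t (1 − (1 − πr²/A)^{n_a})` ignores edge effects; the point-pattern
generator therefore keeps anchors one attraction radius away from the field
edge so the closed form is exact in calibration tests. Images are analysed
independently and then pooled.

## Repertoire statistics

SHM bins: 0 → none, (0, 0.02] → low, > 0.02 → high. Clonal diversity is the
Shannon entropy of clone-size proportions normalised by `ln k` (k =
clonotype count in the cluster), so diversity = 1 − expansion lies in
[0, 1], is 0 for a single clonotype and 1 for all-singletons. The
transition index between two clusters is the clone-size-weighted mean of
each spanning clonotype's split entropy normalised by ln 2 — 0 with no
spanning clonotype, 1 when every clonotype splits evenly; it is symmetric
by construction. Top-k sharing takes the reference cluster's k largest
clonotypes (ties by lexicographic id for determinism, k = 10) and reports,
per cluster, the fraction of cells carrying one of them. The cited
expansion/transition indices exist in several normalisations (log base,
pooling); the conventions above are this package's documented defaults,
not a claim about any other implementation.

## Germinal-centre axis

GC B cells cycle between dark and light zones, so their states form a loop:
mean-centred expression of a curated panel is projected onto PC1/PC2 and
converted to polar coordinates, `θ = atan2(PC2, PC1)` in [0, 2π), `ρ` the
PC-plane norm plus a constant offset that moves cells off the pole (default:
the 5th percentile of the raw radii — enough to clear the origin without
distorting relative radii). PCA signs are fixed so the gene with the largest
absolute loading on each component loads positively; without this the
embedding flips arbitrarily between runs. The curated panel and DZ/LZ gene
lists are runtime inputs. Axis quality is measured by the Fisher–Lee
T-linear circular correlation (pairwise-difference form, well defined even
for uniformly spread angles; rotation-invariant, sign-flipping under
reflection — validation uses its magnitude since a reflection of the PC
plane is geometrically immaterial).

## Survival stratification

The TLS-CS matrix is the per-sample ssGSEA score of the seven TLS
signatures (Naive_B, Memory_B, GC_B, Plasma, CD4_C8_CXCR5, CD8_C8_CXCL13,
iCAF_C2_CXCL13), z-standardised per signature. Patients split into two
modules by Ward/Euclidean hierarchical clustering cut at k = 2 (the module
heatmap's visual two-block structure, made explicit; clustering runs on a
canonically sorted copy so the split is invariant to sample order), with the
module of greater mean aggregate score labelled "high" — removing label
ambiguity deterministically. A score-threshold alternative is available via
`roc_optimal_cutoff`, which scans midpoints between sorted unique scores and
maximises Youden's J (ties to the smallest threshold; closest-to-corner
criterion by flag). Kaplan–Meier, log-rank and Cox (Efron tie handling,
Wald CI/p) are delegated to lifelines behind this module's surface and are
cross-checked in the tests against a hand product-limit fixture and a
grid-search partial-likelihood oracle. Complete separation is detected,
flagged, and the coefficient capped at |β| = 20.

## The synthetic-data generator

The generator produces every input the pipeline consumes, with ground
truth. The spatial model plants disc-shaped compartments on the grid and
draws counts NB(μ, θ) with Var = μ + μ²/θ (gamma–Poisson, θ = 2 by
default — moderate overdispersion typical of spot data). Relative
expression is 1 per gene times: a per-gene log-normal baseline (σ = 1,
giving the broad expression distribution real tissue has — without it,
marker genes would occupy expression bins alone and control-matched scoring
would degenerate); the marker fold-change (default 8) inside the matching
region; an EBV scale of 3^{0,1,2} for low/mid/high aggregates; a plasma
programme in TLSs and plasma-flagged (wP) aggregates; and an apoptosis
uplift in TCAs of 2.0× for wP times {1.0, 1.35, 1.8} for EBV low/mid/high —
encoding the plasma-linked, EBV-amplified apoptosis coupling the analysis
is designed to detect, with EBV-high-wP highest by construction. Per-spot
depth is log-normal around 5000 UMIs (σ = 0.3) so normalisation is
genuinely exercised.

The default tissue is a 40 × 40 hexagonal grid with 10 TCA discs (radius 3
spots; EBV levels planted at 30/40/30 % spot proportions so quartile
stratification has a recoverable truth; plasma flags alternating so all
four EBV × plasma classes occur) and 7 TLS discs, chosen so that
plasma-elevated spots (TLSs plus wP aggregates) exceed a quarter of the
grid — the 0.75-quantile occupancy rule then separates wP from woP cleanly.
Discs are spaced ≥ 2 pitches apart so planted aggregates map 1:1 to
connected components.

Repertoires draw private clone sizes from a Zipf law (exponent 2); sharing
`(ref, other) → rate` makes each cell of `other` adopt, with that
probability, a size-weighted clonotype from `ref`'s top-10 pool, so the
configured rate is exactly the expected top-10 sharing fraction measured
downstream. SHM is Beta(0.6, 15) with a 15 % point mass at zero; isotypes
are i.i.d. categorical. Point patterns place a configurable fraction of
targets uniformly inside the attraction radius of a random anchor. Survival
cohorts are two equal-probability groups with exponential event times
(baseline hazard 0.05/month; the high group's hazard multiplied by
`exp(β)`, default β = ln 0.3) and independent Uniform(0, c) censoring with
c solved by root-finding so the expected censored fraction matches the
requested rate.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: cell-type mixtures within spots and diffuse
compartment boundaries (discs are crisp), spatial autocorrelation of
background expression, batch and section effects, doublets and ambient RNA,
receptor sequence evolution (clonotypes are opaque ids), and the joint
dependence of censoring on covariates. Recovery rates on simulated tissue
are upper bounds on real-data performance.

## Problem sizes and determinism

All generators and scoring functions are deterministic given their seed.
The validation suite uses: 1600-spot default tissues (single samples for
recovery, 100 replicates for the apoptosis-ordering rate), a 2000 × 1000
homogeneous matrix with 200 random 50-gene signatures for module-score
calibration, 100 random proximity instances (n ≤ 2000) against an O(n²)
oracle plus a 10⁴-point CSR calibration, 500-cell/40-gene cyclic data for
the GC axis, 200 replicate n = 150 cohorts for hazard-ratio detection and
200 null cohorts for Wald-p calibration (500 in the unit suite). These
sizes were chosen to keep Monte-Carlo error well below the tested margins.

## Known limitations

- The region caller is marker-driven only; no morphology or image channel
  enters the decision.
- The EBV three-class scheme is applied uniformly; cohorts scored with an
  EBV-gene signature versus a DEG surrogate signature are not distinguished
  by the code.
- `cluster_two_modules` assumes the two-module structure exists; it will
  split any non-degenerate cohort into two groups.
- Proximity statistics are 2-D Euclidean with no edge correction.
- The seven TLS signature gene lists, the GC panel and DZ/LZ lists are
  runtime inputs; the package ships only the short printed marker lists in
  `tlsniche.signatures`.
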