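# tlsniche

Spatial and repertoire analysis of **tertiary lymphoid structures (TLS)**
and **tumour-cell aggregates (TCA)** in EBV-associated carcinoma, built for
spatial transcriptomics (10x Visium, Stereo-seq bin100), single-cell
RNA/BCR/TCR data, multiplex-imaging cell tables and bulk-expression survival
cohorts.

TLSs are ectopic aggregates of B and T cells (sometimes with germinal
centres) inside tumour tissue. In EBV-driven cancers such as nasopharyngeal
carcinoma, plasma cells spatially co-occurring with EBV-high tumour-cell
aggregates associate with tumour-cell apoptosis, and the joint abundance of
seven TLS-associated cell types (the **TLS cell signature, TLS-CS**)
stratifies patient survival. `tlsniche` implements that analysis chain as a
tested, reusable library, together with a synthetic-data generator that
plants every effect with known ground truth so the whole pipeline is
verifiable end to end.

## What it computes

- **Scoring** (`tlsniche.scoring`) — QC filtering (≥1001 UMIs, ≥501 genes,
  ≤25 % mitochondrial UMIs), log-normalisation, control-bin **module
  scores** (mean expression of a gene set minus expression-bin-matched
  controls), **ssGSEA** per-sample enrichment (rank-weighted running sum,
  α = 0.25), one-vs-rest Wilcoxon/Bonferroni marker ranking with a
  log2FC ≥ 0.25 floor, top-100-DEG signatures, and the Livak 2^−ΔΔCt
  relative EBV DNA load.
- **Compartments** (`tlsniche.compartments`) — Stereo-seq bin100
  aggregation (100×100 spots ≈ 49.72 µm), TLS/TCA/stroma calling from
  z-standardised malignant/B/T scores, connected TCA components, EBV
  stratification by spot-level quartiles (>Q3 high, <Q1 low), plasma
  co-occurrence (wP/woP), apoptosis comparison across classes, normalised
  interaction values, immune-infiltration bins.
- **Proximity** (`tlsniche.proximity`) — exact within-radius counts
  (20 µm default, closed boundary), nearest-neighbour distance histograms,
  and the complete-spatial-randomness expectation
  `n_t · (1 − (1 − πr²/A)^{n_a})`.
- **Repertoire** (`tlsniche.repertoire`) — SHM bins (0 → none,
  (0, 0.02] → low, >0.02 → high), isotype composition, normalised Shannon
  clonal diversity `H/ln k` (= 1 − expansion), the clone-size-weighted
  transition index, top-k clonotype-sharing fractions.
- **GC axis** (`tlsniche.gc_axis`) — germinal-centre circular embedding:
  mean-centred PCA of a curated panel, polar conversion with a radial
  offset, dark-/light-zone module scores, circular correlation.
- **Survival** (`tlsniche.survival`) — TLS-CS score matrix (ssGSEA over the
  seven TLS signatures, z-scored), two-module Ward clustering, ROC/Youden
  cutoffs, Kaplan–Meier, log-rank and Cox proportional hazards (Efron ties).
- **Simulation** (`tlsniche.simulate`) — negative-binomial spatial samples
  on hex (100 µm) or square (49.72 µm) grids with planted compartments,
  marker single cells, clonal repertoires with controllable sharing, point
  patterns with controllable attraction, survival cohorts with
  signature-dependent hazards — all with ground truth and seeded
  determinism.

## Worked example

```python
import pandas as pd
import tlsniche as t

cfg = t.simulate.default_spatial_config(seed=1)      # 40x40 hex, 10 TCA + 7 TLS discs
adata, truth = t.simulate.generate_spatial_sample(cfg)
ln = t.scoring.log_normalize(adata)
scores = pd.DataFrame({r: t.scoring.module_score(ln, truth.signatures[r], seed=0)
                       for r in ("malignant", "B", "T", "EBV", "plasma", "apoptosis")})
regions = t.compartments.call_regions(scores[["malignant", "B", "T"]])
grid = t.compartments.SpotGrid.from_anndata(adata)
comps = t.compartments.find_tca_components(regions, grid)
_, ebv = t.compartments.stratify_ebv(comps, scores["EBV"])
plasma = t.compartments.classify_plasma_cooccurrence(comps, scores["plasma"], grid)
print(t.simulate.score_region_call(truth, regions))
print(t.simulate.score_component_classes(truth, comps, ebv, plasma))
```

prints

```
0.99875
1.0
```

i.e. 99.88 % of the 1600 spots get their planted TLS/TCA/stroma label back,
and all 10 planted tumour aggregates are typed correctly on both axes
(EBV high/mid/low × with/without plasma cells). Comparing apoptosis module
scores across the four EBV × plasma classes
(`t.compartments.compare_apoptosis`) then ranks `high-wP` — EBV-high
aggregates with plasma cells — highest, the spatial coupling the pipeline is
designed to detect.

A thin CLI mirrors the library:

```bash
tlsniche simulate-spatial out/ --seed 1
tlsniche score out/ out/signatures.json scores.csv --kind modules
tlsniche call-compartments scores.csv out/matrix.coords.csv map.csv
```

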