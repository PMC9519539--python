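# dcisime

Compartment-resolved profiling of the immune microenvironment in DCIS
(ductal carcinoma in situ) slides, from multiplexed marker flags to
case–control inference:

- **`dcisime.synthetic`** — synthetic slide/cohort generator: ducts as
  epithelial disks with periductal stroma annuli, homogeneous Poisson
  immune subsets per compartment (optional intensity decay toward duct
  boundaries), seeded TLS-like B-cell follicles with T-cell rings, a
  separate CD8/Ki67 double-stain point pattern, patient-level lognormal
  heterogeneity and a configurable case-vs-control effect (default null).
- **`dcisime.io`** — CSV cell tables + GeoJSON compartment geometry,
  schema validation, point-in-polygon compartment assignment with a
  documented precedence tie-break, patient metadata.
- **`dcisime.phenotyping`** — deterministic gating of marker flags
  (panCK, CD3, CD8, CD20, FOXP3, CD68; Ki67 on the double-IHC assay)
  into phenotype labels, plus subset counting including the pooled
  lymphocyte group in strict-literal and inclusive modes.
- **`dcisime.spatial`** — densities in cells/mm² per subset ×
  {stroma, epithelium}, all 28 unordered pairwise subset ratios, and a
  DCIS proximity index (immune cells within 25 µm of any DCIS cell,
  divided by the number of DCIS cells; KD-tree backed).
- **`dcisime.tls`** — zone-TLS (B-cell follicle + adjacent T-cell zone)
  and GC-TLS (Ki67⁺ germinal centre) detection by density clustering,
  and TLS densities per mm².
- **`dcisime.stats`** — permutation Mann–Whitney and Kruskal–Wallis
  tests (exact enumeration for small groups, add-one Monte-Carlo
  otherwise), Benjamini–Hochberg FDR, McGraw–Wong two-way ICC with
  F-based CIs, Spearman correlation, TIL-percentage binning,
  complete-linkage clustering of log(1+x) densities, and a full
  case–control / clinicopathological contrast suite.
- **`dcisime.pipeline`** — YAML-configured end-to-end runs emitting tidy
  CSV tables and a reproducibility log.

## CLI

```bash
# one synthetic slide
dcisime simulate slide --spec slide.yaml --out out/slide --seed 7

# a case/control cohort
dcisime simulate cohort --spec cohort.yaml --out out/cohort --seed 7

# a subjects × raters score matrix
dcisime simulate raters --spec raters.yaml --out out/raters --seed 7

# the analysis pipeline
dcisime profile run --config pipeline.yaml
```

Pipeline config sketch:

```yaml
slides:
  - {patient_id: P000, cells: P000_cells.csv, geometry: P000_geometry.geojson}
metadata: metadata.csv
output_dir: results/
seed: 1
analyses: {densities: true, ratios: true, proximity: true, tls: true, stats: true}
params:
  formula_mode: strict-literal   # or: inclusive
  proximity_radius_um: 25.0
  n_perm: 2000
  tls: {eps_um: 30, min_follicle: 20, t_zone_um: 50, min_t_zone: 30, gc_threshold: 0.3}
```

## Conventions

Coordinates are µm with the origin at the slide top-left and y
increasing downward; areas are mm²; densities are cells/mm². Cells are
centroids. Debris and background compartments are excluded from every
metric. One root seed drives all randomness; cohort slides derive child
seeds via `numpy.random.SeedSequence.spawn`.
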