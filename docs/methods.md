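# Methods

## The evidence model

Published case-control studies of circulating miRNAs in ischemic stroke
rarely report comparable effect sizes: platforms, normalizations and
analysis pipelines differ, and many papers publish only the direction of
dysregulation with the group sizes. `strokemir` therefore aggregates the
*qualitative* evidence with an event-count (vote-counting) odds-ratio model:
a study calling miRNA *i* "up" in `n_case` cases vs `n_control` controls
contributes the 2×2 table (A, B, C, D) = (n_case, 0, 0, n_control), and a
"down" call contributes the transpose (0, n_case, n_control, 0). Controls
are never dysregulated by construction, so two cells of every table are
structurally zero.

This encoding deliberately treats the study's call as if every subject
exhibited it. The resulting pooled log odds ratio is **not** an estimate of
a biological odds ratio; it is a sample-size-weighted consensus score whose
sign gives the consensus direction and whose Wald test asks whether the
directional evidence is stronger than its between-study inconsistency.
Conflicting directions inflate τ² and drive the pooled effect toward zero
(see the serum hsa-miR-22-3p and hsa-miR-23a-3p groups, with I² ≈ 95% and
non-significant pooled effects).

### Estimation details

- Continuity: 0.5 is added to **all four cells** of any zero-containing
  table (configurable amount). The all-cells dialect — not zero-cells-only —
  is what standard meta-analysis software applies and is required for the
  Woolf variance of the corrected table to be well defined; every event
  table in this model contains zeros, so the correction always fires.
- Per-study effect: θ_i = ln(a·d/(b·c)); variance v_i = 1/a + 1/b + 1/c + 1/d
  over the corrected cells.
- Heterogeneity: Cochran's Q with fixed weights 1/v_i;
  τ²_DL = max(0, (Q − df)/C), C = Σu − Σu²/Σu (default). A restricted
  maximum-likelihood (REML) fixed-point estimator is available
  (`tau2_method="reml"`); it matches DL to 4 decimals on every two-study
  group of the packaged catalog and differs only on the three-study serum
  hsa-miR-23a-3p group (76.50 vs 76.03), where REML corresponds to the
  default of the reference R implementation. I² is reported as
  100·τ²/(τ² + s²) with s² = df/C, which reduces exactly to 100·(Q − df)/Q
  for DL.
- Pooling: weights W_i = 1/(v_i + τ²), pooled effect Σ W_i θ_i / Σ W_i,
  se = (Σ W_i)^(−1/2), CI at the two-sided normal 0.975 quantile
  (1.959964…), p from the two-sided normal tail. No Knapp–Hartung
  adjustment; this matches the provenance of the reproduced results table.
- Qualification: a (canonical miRNA, specimen) group needs ≥ 2 distinct
  studies of the same blood element. Cross-stratum evidence never pools; a
  miRNA qualifying in two strata yields two independent groups. Duplicate
  (study, miRNA) rows are rejected at read time rather than merged — no such
  case exists in the curated catalog, and silent merging would hide curation
  errors.
- Name standardization uses a packaged static alias table (reported name →
  canonical mature name) standing in for a live miRBase lookup. It was
  curated by reconciling the catalog's reported spellings against the mature
  names under which the studies group (e.g. miR-487 → miR-487b-3p,
  miR-320a-3p → miR-320a, miR-219-5p → miR-218-5p, bare validation names →
  their -5p/-3p mature forms). The map must be total over the catalog;
  unknown names are hard errors.

### Known non-reproducible rows

Four rows of the published meta-analysis table cannot be derived from the
published per-study inputs under any estimator dialect we tested and are
reported as computed, not special-cased: the plasma hsa-miR-126-3p pooled
effect (−9.51 here vs −9.92 printed), the whole-blood hsa-miR-144-3p
heterogeneity (τ² 70.72 vs 57.53), the serum hsa-miR-9-5p sign (both
contributing studies report "down", so the pooled effect is negative), and
the serum hsa-miR-451a membership (a third qualifying study exists and is
included here, shifting the row to logOR 9.25 from the printed two-study
8.96).

## qPCR validation

Relative expression is (mean spike-in Ct − target Ct) per sample after
averaging technical replicates; with three exogenous spike-ins
(cel-miR-39/54/238) this orientation makes more abundant targets more
positive and gives fold change = 2^ΔΔCt directly. Group "±" values are
SEMs: with n = 20 per group, summary-statistic Student t-tests (sd =
SEM·√n, pooled variance, df = 38) reproduce the published p-values, which
they do not under an SD reading. The t-test is equal-variance by
declaration of the source analyses, not Welch. No replicate-outlier
rejection, efficiency correction, or multiplicity adjustment across the 12
validated targets is applied (none was applied upstream).

## ROC panels

AUC is the midrank Mann–Whitney statistic; the ROC curve sweeps unique
thresholds, and its trapezoidal area equals the rank AUC to 1e-12 by
construction. Panels are scored by the linear predictor of a logistic
model fitted by IRLS (tolerance 1e-8 on the step, max 100 iterations).
Perfect separation is flagged with a warning and the iteration-cap
coefficients are returned: the score ordering, which is all ROC needs, is
already stable. The default is in-sample AUC, matching the provenance of
the published single-marker values; a stratified k-fold mode (seeded) is
available for honest out-of-sample estimates, and the null-panel test uses
it for exactly that reason. Single-marker AUCs below 0.5 trigger an
orientation warning rather than an automatic flip.

## Tissue profiles

Samples are averaged within tissue first, then each miRNA column is
standardized across tissues ((x − mean)/sd, sd with n−1 denominator).
Averaging-first matches the stated order of the upstream analysis.
Constant columns map to zero z-scores with a warning. Quantile
normalization is assumed to have happened upstream (tissue atlases ship
normalized data) and is not re-implemented.

## Enrichment

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) for overlap k between the query (union of validated target genes
of the chosen miRNAs) and each gene set, within a universe defaulting to
all collection genes plus the query (an explicit background list can be
supplied — the appropriate universe is a genuine modelling choice the user
should own). BH adjustment is applied per collection; significance is
p_adj < 0.05. Published pathway counts depend on database versions and are
not asserted against packaged collections.

## Synthetic data

The generators encode the designs of the studies they emulate:

- **Catalog generator** — 29 studies by default with the curated catalog's
  specimen frequencies (14/7/6/2 over serum/plasma/whole blood/PBMCs),
  per-miRNA consensus directions, an agreement probability governing how
  often a study's call matches the consensus, and uniform group sizes in
  10–300 (the catalog's range).
- **Ct generator** — per-sample reference level ~ N(20, 0.5) on the Ct
  scale (typical spike-in cycle counts), three spike-in wells and
  triplicate target wells with technical sd 0.1, and per-target biological
  effects on the log2 scale, consistent with ΔΔCt arithmetic. The `paper`
  preset plants each target's published group-mean difference and chooses
  per-group biological sd so that the *total* per-sample variance equals
  n·SEM² from the packaged summaries (technical variance /replicates is
  subtracted out), i.e. the generator reproduces the published 20 vs 20
  design's first two moments by construction.
- **Target/gene-set generator** — one planted gene set sampled with
  configurable weight toward the miRNA target union, the rest uniform.
- **Tissue generator** — 31 tissues × 2 samples with one planted
  tissue-specific miRNA.

What the generators do not emulate: correlated co-regulation between
miRNAs (targets are independent given the design, apart from shared
spike-in noise), heavy-tailed or batch-structured Ct noise, hemolysis
artefacts, platform effects between studies, and publication bias in which
studies exist at all. Passing recovery tests therefore demonstrates the
pipeline's correctness and calibration under the declared model, not
robustness to those real-data pathologies.

A consequence of faithful calibration worth stating plainly: the published
validation t-statistics imply per-target replication power of roughly
0.74/0.69/0.90/0.52 for the four validated miRNAs at n = 20 + 20, so a
simulation calibrated to those summaries detects all-but-one of the
planted effects in only ~70% of replicates. The generator reports what the
design supports; it is not tuned to flatter the pipeline.

## Numerical and engineering choices

- All estimators are deterministic; every stochastic component takes an
  explicit seed and regenerates byte-identically.
- Hypergeometric tails come from scipy's log-space survival function; BH
  from statsmodels; summary t-tests from scipy's
  `ttest_ind_from_stats`. The meta engine, rank AUC and IRLS fit are
  implemented here and cross-checked in the test suite against independent
  oracles (closed-form arithmetic, exhaustive pair counting and
  enumeration, and scikit-learn's AUC).
- Report rounding mirrors the reproduced tables: logOR/CI/τ²/I²/weights to
  2 decimals, p in scientific notation with 3 significant digits.
- Degenerate inputs are contracts, not surprises: zero-variance t-tests
  return p ∈ {0, 1} with a degeneracy flag, constant tissue columns return
  zero z-scores with a warning, empty catalogs yield empty outputs, and
  malformed rows (unknown specimen, non-positive group size, duplicate
  reports, partial alias coverage, missing spike-ins) are hard errors
  naming the offending row or sample.

## Problem sizes

The packaged analyses are desk-scale (29 studies, ≤ 4 studies per group,
12 validation targets) and run in well under a second each. The
simulation-based test batteries use 100–500 seeded replicates of 20–40
sample designs, chosen to keep Monte-Carlo error on assessed rates near or
below one percentage point while the full suite completes in seconds.
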