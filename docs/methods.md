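# Methods

This note records the models, numerical choices and open design decisions
behind each stage of the toolkit, and what the synthetic fixtures do and do
not establish about real tissue.

## Synthetic data model

**Intensities.** Marker expression lives on a fixed [0, 1] scale so that the
pan-immune CD45 > 0.07 cut-off is directly meaningful. Each phenotype
archetype assigns every panel marker a sign; a "+" marker is sampled around
`mean_high` (default 0.5) and a "−" marker around `mean_low` (default 0.03)
with unit-mean multiplicative lognormal noise (`dispersion` = 0.25, i.e.
σ of log-intensity), clipped to [0, 1]. Lognormal noise is positive-valued
and its dispersion directly controls the overlap between positive and
negative populations; with the defaults the populations are well separated
(gating recovers planted labels essentially exactly), which is deliberate —
the fixtures test the machinery, not threshold robustness.

**Archetypes and stages.** One archetype per terminal phenotype of the
gating tree (CD8⁺ and proliferating CD8 T cells, Tregs and proliferating
Tregs, other Th, B cells, CD1C⁺ dendritic cells, CD163± myelomonocytic
cells, CD68⁺CSF1R⁻ monocytes/macrophages) plus a CD45-negative epithelial
archetype. Stage compositions plant the biology the analysis stages must
detect: immune infiltration, the Treg fraction and the CD163⁺
myelomonocytic fraction all rise monotonically from NSQ to EAC (epithelial
fraction 70 → 50%, Treg 1 → 8%, CD163⁺ myelo 1 → 10%). The default cohort
is 2 ROIs per stage, 350–400 cells per 400 × 400 µm ROI (≈ 2,200 cells/mm²,
a realistic tissue density); these sizes keep every stage exercisable at
desk scale while preserving the planted trends.

**Rendering.** Nuclei are ellipses (radii 2.6–3.8 µm, random orientation)
with hematoxylin absorbance ≈ 0.85; each marker round adds an AEC disk
(1.3 × the nucleus radius) whose absorbance equals the cell's intensity, so
deconvolution is exactly invertible up to noise. Pixels follow Beer–Lambert:
`RGB = 255 · exp(−Σ cₛ vₛ)` with unit OD stain vectors (natural log
convention throughout). A smooth seeded stromal absorbance field (Gaussian
field, σ = 3 µm, peak OD 0.18, along the hematoxylin vector, identical
across rounds because it is the same tissue) supplies the distinctive
gradients feature matching needs — without it, nuclei are too self-similar
and descriptor matching degrades, exactly as blank tissue would in reality.
Additive Gaussian pixel noise (σ = 1.5 grey levels) is drawn per round. The
renderer does not attempt photorealism: no stain bleed, no cycle carryover,
no 3-D structure, no out-of-focus blur. Passing tests therefore demonstrate
correctness of the computational chain under the stated forward model, not
robustness to every histological artifact.

## Registration

Transform family is similarity (scale, rotation, translation) — the
distortion mIHC re-scanning actually introduces; full affine is not fitted.
ORB keypoints (1,500 per image, FAST threshold 0.05) on the grayscale
raster are matched by Hamming distance with cross-checking; RANSAC
(min sample 3, inlier threshold 2 px, seeded) rejects outliers, followed by
two rounds of trimmed least squares (Umeyama fit, re-selecting inliers at
2 px then 1.5 px), which brings the planted-transform recovery error to
≈ 0.5 px at the image corners. Featureless inputs raise an explicit
"insufficient features" error rather than silently returning identity.
Aligned rounds are resampled bilinearly (nearest-neighbor for label masks)
and cropped to the largest axis-aligned rectangle valid in every warped
round. Coordinates are 0-based pixels, x = column, y = row, origin top-left;
µm = px × 0.22.

## Deconvolution, segmentation, quantification

Stain separation inverts the 3 × 3 OD basis (AEC, hematoxylin, and their
cross product as residual; defaults are the standard Ruifrok–Johnston
hematoxylin vector and the ImageJ AEC vector), clips negative
concentrations, and rescales by a fixed reference OD of 1.0. A CMYK
heuristic mode (AEC ≈ magenta) is provided behind a flag for fidelity with
legacy ImageJ-macro pipelines but is less well conditioned and not used by
default. Segmentation: Gaussian smoothing (σ = 0.7 µm), Otsu threshold
(override available), removal of components under 8 µm², watershed on the
negated distance transform seeded at distance maxima ≥ 2.5 µm apart, with
seeds ordered by raster position so labelling is deterministic. Per-cell
statistics use the unweighted nucleus-pixel mean (no cytoplasm ring; an
optional dilation is out of scope). The open question of background
subtraction before averaging is resolved as "none": the deconvolution's
blank-field zero makes it unnecessary under the forward model.

## Gating

Positivity is strict (`>`), thresholds are per-marker configuration values
(0.2 by default for lineage markers on the [0, 1] scale, 0.07 for CD45);
no threshold beyond CD45's is treated as externally given, since manual
image cytometry does not publish its gates. Rules are evaluated in order,
first full match wins, and the shipped config orders rules
most-specific-first with pan-immune and non-immune catch-alls closing the
partition, so ancestor populations (total T cells, total myelomonocytic
cells, pan-immune) are expressed as label groups used by the
density/proportion summaries rather than as reachable rules. The spatial
gate rasterizes the epithelial region at 1 µm, takes a Euclidean distance
transform, and keeps cells within the margin (default 200 µm) — one code
path for polygon and mask inputs alike.

## Sparse subspace clustering

The ℓ1 self-expressiveness program is relaxed to per-cell Lasso over a
landmark dictionary: minimize ½‖xᵢ − D cᵢ‖² + λᵢ‖cᵢ‖₁ with the
self-column removed for landmark cells (the cᵢᵢ = 0 constraint). λᵢ is
scaled per cell as α·‖Dᵀxᵢ‖∞ with α = 0.05 — the natural scaling, since
‖Dᵀxᵢ‖∞ is the smallest λ with an all-zero solution. Landmarks default to
min(2000, N) k-means representatives (nearest real cell per center,
deterministic per seed). Affinity: with all cells as landmarks, the classic
W = |C| + |C|ᵀ; otherwise two cells are similar through shared landmark
support, W = ĈᵀĈ with ℓ2-normalized |C| columns — the landmark-to-graph
lift is a design choice recorded in the model diagnostics. Clustering uses
the normalized-Laplacian embedding (top-k eigenvectors, row-normalized) and
seeded k-means. Feature normalization (none / per-marker max / z-score) is
configurable and defaults to none, as the shared [0, 1] scale already makes
markers commensurate. Default k = 20 groups for cohort runs; `choose_k`
computes the within-cluster sum of squares of k-means in a
squared-eigenvalue-weighted ("diffusion") spectral embedding over the
candidate range and takes the kneedle-style elbow — the point of maximum
drop below the chord of the normalized curve — returning the smallest
candidate when no point falls more than 0.5 below the chord (no genuine
elbow). Low-intensity "unclassified" groups are left to user
interpretation; the algorithm only outputs groups and profiles.

## Spatial statistics

The knn graph (k = 10, Euclidean µm between nucleus centers, self
excluded, ties broken by cell index) is fixed while phenotype labels are
shuffled 1,000 times with a seeded generator. The pair statistic is the
mean number of target-labelled neighbors over reference-labelled cells;
z = (obs − mean_perm)/sd_perm, and the p-value is the empirical two-sided
tail probability with the +1 correction, p = (#{|perm − mean| ≥ |obs −
mean|} + 1)/(n_perm + 1) — a proper probability, preferred over a scaled
effect-size convention; both z and p are reported so either can be
inspected. Calls: enriched if p < α and obs above the null mean, depleted
if below, ns otherwise (α = 0.05; no multiple-testing correction by
default, matching common neighborhood-analysis practice — Benjamini–
Hochberg can be applied downstream). The matrix is directional by
construction and is never symmetrized. Under random labels the test is
well calibrated (≈ 5% of pairs called at α = 0.05; p-values near-uniform),
verified by simulation. Stage aggregation averages z element-wise across a
stage's ROIs, skipping not-evaluable pairs and reporting the contributing
ROI count.

## Stage statistics and report

Mann–Whitney–Wilcoxon is exact (full enumeration) when the pooled sample
is ≤ 12 and tie-free, otherwise the tie-corrected normal approximation;
two identical constant groups are defined as U = n₁n₂/2, p = 1 (no ordinal
information). The Bonferroni family is the set of tested stage pairs per
population — the family is configurable because the choice between "all 6
stage pairs" and "pairs actually examined" is a reporting convention, not
a statistical necessity; the default is the tested pairs. Stars are
computed from the adjusted p by default (a flag selects raw-p stars).
Kruskal–Wallis uses the tie-corrected H with a χ² reference (df = groups −
1), with the all-identical degenerate case defined as H = 0, p = 1. The
report bundle (tidy CSVs, per-population stage plots with star
annotations, cluster-profile and enrichment heatmaps) is deterministic for
fixed inputs.

## Problem sizes

Defaults used by the test suite and the acceptance script: one rendered
image ROI of 100 cells at 130 × 130 µm (591 × 591 px) with 11 rounds; a
table cohort of 8 ROIs × 350 cells; SSC benchmarks at N = 600 (planted
subspaces) and ≈ 1,200 immune cells (archetype concordance) with 100–200
landmarks; enrichment calibration at N = 2,000 cells, 1,000 permutations,
50–200 replicates. These sizes preserve every qualitative property being
tested (registration accuracy, watershed behavior, subspace recovery,
test calibration, planted stage trends) at desk scale; absolute cohort
magnitudes (hundreds of thousands of cells) are not reproduced and no
claim depends on them.

## Known limitations

- The renderer's noise model is additive Gaussian at the pixel level and
  lognormal at the cell level; it does not emulate stain bleed-through,
  incomplete stripping between cycles, folds, or scanner vignetting.
- Gating thresholds are configuration, not calibrated values; on real data
  they must be set per batch (an automatic bimodal-split helper would be a
  natural extension but is intentionally not a default).
- SSC assumes marker vectors concentrate near a union of low-dimensional
  subspaces; heavily mixed or continuous phenotypes violate this and the
  elbow rule will simply report weak structure.
- ROIs are treated as independent sample points in all stage statistics;
  patient-level nesting is out of scope.
- Registration is rigid-similarity only; tissue that deforms non-rigidly
  between rounds needs a deformable method upstream.
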