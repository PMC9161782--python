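# mihckit

Analysis toolkit for **sequential chromogenic multiplex immunohistochemistry
(mIHC)** — the iterative stain/image/strip protocol that detects ~10 protein
markers on a single FFPE tissue section using the red AEC chromogen with a
hematoxylin nuclear counterstain. It is written for computational biologists
and image-analysis scientists who need to turn per-round brightfield scans of
annotated tissue regions (ROIs) into quantitative single-cell immune
profiles, for example when tracking how regulatory T cells and CD163⁺
myelomonocytic cells expand across the esophageal disease sequence
NSQ → NDBE → Dys → EAC (normal squamous epithelium, non-dysplastic Barrett's
esophagus, dysplasia, adenocarcinoma).

The pipeline covers, end to end:

1. **Co-registration** of the per-round RGB rasters (0.22 µm/px) by ORB
   feature matching and a RANSAC-robust similarity fit (scale, angle,
   translation), cropped to the common valid region.
2. **Chromogen deconvolution** in optical-density space: per pixel,
   `OD = −log(I / I₀)` is projected onto the AEC/hematoxylin stain basis
   (Beer–Lambert unmixing), giving an AEC intensity per marker and a nuclear
   hematoxylin channel on a fixed [0, 1] scale.
3. **Watershed nuclear segmentation** (distance-transform seeds on the
   hematoxylin channel) and **single-cell quantification**: per cell, the
   centroid (µm), nucleus area, and mean deconvolved AEC intensity per
   marker.
4. **Hierarchical gating**: an ordered list of marker-sign rules
   (e.g. CD45⁺CD3⁺CD8⁻FOXP3⁺ → T regulatory cells) evaluated
   first-match-wins with strict `intensity > threshold` positivity; includes
   a 200 µm stromal-margin spatial gate around the epithelium and per-ROI
   densities (cells/mm²) and proportions.
5. **Sparse subspace clustering (SSC)** for automated phenotyping of the
   immune compartment (CD45 > 0.07). Each cell's marker vector is
   self-expressed over landmark cells,

   min‖cᵢ‖₁ subject to xᵢ = X cᵢ, cᵢᵢ = 0,

   solved in practice as the Lasso relaxation
   ½‖xᵢ − D cᵢ‖² + λ‖cᵢ‖₁ over a landmark dictionary `D`; the sparse codes
   define a symmetric affinity that is spectrally clustered into `k` groups
   (default 20; an elbow rule is available).
6. **Spatial statistics**: mean shortest reference→target distances with
   30/50 µm proximity fractions, and k-nearest-neighbor (k = 10)
   **neighborhood enrichment** against a 1,000-permutation random-label
   null, reported as z-scores and empirical two-sided p-values with
   enriched/depleted/ns calls.
7. **Stage comparisons**: two-sided Mann–Whitney–Wilcoxon with Bonferroni
   correction (one ROI = one sample point), Kruskal–Wallis screening, the
   conventional star ladder (ns > 0.05, * ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001,
   **** ≤ 0.0001), and a CSV + figure report bundle.

Because no public dataset accompanies this assay, the package ships a
first-class **synthetic-data module**: phenotype archetypes (marker-sign
combinations with lognormal intensity noise), spatial layouts (uniform,
clustered, two-block, epithelium/margin), and a full brightfield renderer
(hematoxylin ellipse nuclei, AEC chromogen disks, stromal texture, per-round
similarity distortions, pixel noise) with complete ground truth — every
pipeline stage is validated against planted truth.

## Worked example

`examples/02_register_and_quantify.py` renders one ROI (100 cells, 11
rounds) with a known distortion planted on round 2, then runs registration →
deconvolution → segmentation → quantification:

```
planted : scale=1.0200 angle=3.000deg shift=(10.0, -5.0) px
recovered: scale=1.0194 angle=3.040deg shift=(10.4, -4.9) px
nuclei rendered: 100, segmented in crop: 94
   cell_id     x_um   y_um  area_um2   CD45    CD3
0        1   13.504  0.802    11.277  0.031  0.036
2        3   57.739  2.701    39.301  0.347  0.602
```

The recovered transform matches the planted one to a fraction of a pixel;
the six cells missing from the count lie outside the common crop. Each row
is one segmented cell with µm coordinates and mean deconvolved marker
intensities — cell 3 is CD45⁺CD3⁺ (a T cell), cell 1 is marker-negative
(epithelial). The other examples each demonstrate one capability
(simulation, gating, SSC, spatial statistics, stage reports) and print a
short interpretation of their output; `mihckit --help` lists the equivalent
shell subcommands.

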