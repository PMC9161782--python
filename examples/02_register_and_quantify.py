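"""Render staining rounds, co-register them, and extract the cell table.

One ROI is rendered as 11 brightfield rounds (hematoxylin + 10 AEC marker
rounds) with a known similarity distortion planted on round 2.  The pipeline
recovers the transform by feature matching, deconvolves the chromogens,
segments nuclei by watershed and quantifies per-cell marker intensities.
"""

import numpy as np

from mihckit.fixtures import (
    MARKER_PANEL,
    default_archetypes,
    render_round_images,
    synth_cell_table,
    synth_tissue_layout,
)
from mihckit.registration import SimilarityTransform, register_stack
from mihckit.stain_quant import deconvolve_stack, quantify_cells, segment_nuclei

table = synth_cell_table(
    default_archetypes(),
    {"CD8+ T cells": 30, "B cells": 30, "Epithelial cells": 40},
    noise_seed=7,
    roi_id="DEMO",
)
scene = synth_tissue_layout(table, "random", (130, 130), seed=1, min_spacing_um=10)

planted = SimilarityTransform(scale=1.02, angle=np.radians(3), translation=(10, -5))
transforms = [SimilarityTransform() for _ in range(11)]
transforms[2] = planted
rounds, truth = render_round_images(scene, round_transforms=transforms, seed=3)

stack = register_stack(rounds, reference_round=0)
est = stack.transforms[2]
print(f"planted : scale=1.0200 angle=3.000deg shift=(10.0, -5.0) px")
print(
    f"recovered: scale={est.scale:.4f} angle={np.degrees(est.angle):.3f}deg "
    f"shift=({est.translation[0]:.1f}, {est.translation[1]:.1f}) px"
)

deconvolve_stack(stack, list(MARKER_PANEL))
mask = segment_nuclei(stack.nuclear, stack.pixel_size_um)
cells = quantify_cells(mask, stack)
print(f"nuclei rendered: {len(table)}, segmented in crop: {mask.n_cells}")
print(cells[["cell_id", "x_um", "y_um", "area_um2", "CD45", "CD3"]].head().round(3))

# The recovered transform matches the planted one to a fraction of a pixel,
# and each table row is one cell with its centroid (µm), nucleus area and
# mean deconvolved AEC intensity per marker on the [0, 1] scale.
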