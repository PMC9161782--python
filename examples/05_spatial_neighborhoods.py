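"""Spatial statistics: shortest distances and neighborhood enrichment.

Places two phenotypes in disjoint tissue blocks, then asks (a) how far each
reference cell is from its nearest target cell and (b) whether each phenotype
is enriched or depleted among each phenotype's 10 nearest neighbors, against
a 1,000-permutation random-label null.
"""

from mihckit.fixtures import default_archetypes, synth_cell_table, synth_tissue_layout
from mihckit.spatial import (
    knn_graph,
    mean_shortest_distance,
    neighborhood_enrichment,
    proximity_fractions,
)

table = synth_cell_table(
    default_archetypes(),
    {"T regulatory cells": 150, "CD163+ myelomonocytic cells": 150},
    noise_seed=3,
)
scene = synth_tissue_layout(table, "two_block", (400, 400), seed=7)
cells = scene.cells.rename(columns={"true_label": "phenotype"})

res = mean_shortest_distance(
    cells, "T regulatory cells", "CD163+ myelomonocytic cells"
)
frac = proximity_fractions(res.distances_um)
print(f"mean shortest Treg -> CD163+ myelo distance: {res.mean_um:.1f} µm")
print(f"fraction of Tregs within 30 µm: {frac[30.0]:.2f}, "
      f"within 50 µm: {frac[50.0]:.2f}")

graph = knn_graph(cells, k=10)
enr = neighborhood_enrichment(
    graph, cells["phenotype"].to_numpy(), n_perm=1000, seed=5
)
print("\nneighborhood enrichment (z > 0 enriched, z < 0 depleted):")
print(
    enr[["reference", "target", "observed", "perm_mean", "z", "p", "class"]]
    .round(3).to_string(index=False)
)

# Because the phenotypes occupy disjoint halves, each is enriched in its own
# neighborhoods and depleted in the other's — the canonical segregated
# pattern; in mixed tissue the matrix is asymmetric (A around B need not
# equal B around A).
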