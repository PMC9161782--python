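# Default hierarchical gating configuration for the 10-marker esophageal
# immune panel.  Rules are evaluated in order; the first rule whose
# marker-sign conjunction fully matches a cell's sign vector assigns the
# phenotype.  Rules are ordered most-specific-first so the list partitions
# the full sign space; the trailing rules are the pan-immune and non-immune
# catch-alls.
thresholds:
  CD45: 0.07
  CD3: 0.2
  CD8: 0.2
  FOXP3: 0.2
  CD20: 0.2
  CD68: 0.2
  CSF1R: 0.2
  CD163: 0.2
  CD1C: 0.2
  KI67: 0.2
rules:
  - label: Proliferating CD8 T cells
    signs: {CD45: "+", CD3: "+", CD8: "+", KI67: "+"}
  - label: CD8+ T cells
    signs: {CD45: "+", CD3: "+", CD8: "+"}
  - label: Proliferating T reg cells
    signs: {CD45: "+", CD3: "+", CD8: "-", FOXP3: "+", KI67: "+"}
  - label: T regulatory cells
    signs: {CD45: "+", CD3: "+", CD8: "-", FOXP3: "+"}
  - label: Other Th cells
    signs: {CD45: "+", CD3: "+", CD8: "-", FOXP3: "-"}
  - label: B cells
    signs: {CD45: "+", CD3: "-", CD20: "+"}
  - label: CD1C+ myeloid dendritic cells
    signs: {CD45: "+", CD3: "-", CD20: "-", CD1C: "+"}
  - label: CD163+ myelomonocytic cells
    signs: {CD45: "+", CD3: "-", CD20: "-", CD1C: "-", CD68: "+", CSF1R: "+", CD163: "+"}
  - label: CD163- myelomonocytic cells
    signs: {CD45: "+", CD3: "-", CD20: "-", CD1C: "-", CD68: "+", CSF1R: "+", CD163: "-"}
  - label: Monocytes, macrophages, fibrocytes
    signs: {CD45: "+", CD3: "-", CD20: "-", CD1C: "-", CD68: "+", CSF1R: "-"}
  - label: Other immune cells
    signs: {CD45: "+"}
  - label: Non-immune cells
    signs: {}
# Composite (ancestor) populations used for density/proportion summaries,
# each expressed as the union of terminal phenotype labels.
groups:
  Pan immune cells:
    - Proliferating CD8 T cells
    - CD8+ T cells
    - Proliferating T reg cells
    - T regulatory cells
    - Other Th cells
    - B cells
    - CD1C+ myeloid dendritic cells
    - CD163+ myelomonocytic cells
    - CD163- myelomonocytic cells
    - Monocytes, macrophages, fibrocytes
    - Other immune cells
  T cells:
    - Proliferating CD8 T cells
    - CD8+ T cells
    - Proliferating T reg cells
    - T regulatory cells
    - Other Th cells
  CD8- T cells:
    - Proliferating T reg cells
    - T regulatory cells
    - Other Th cells
  Presumptive myeloid lineages:
    - CD1C+ myeloid dendritic cells
    - CD163+ myelomonocytic cells
    - CD163- myelomonocytic cells
    - Monocytes, macrophages, fibrocytes
  Myelomonocytic cells:
    - CD163+ myelomonocytic cells
    - CD163- myelomonocytic cells
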