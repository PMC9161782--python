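"""End-to-end orchestration of the mIHC analysis on synthetic cohorts.

``run_pipeline`` exercises every stage in sequence — simulate, render,
register, deconvolve, segment, quantify, gate, cluster, spatial statistics,
stage comparisons, report — writing the intermediate CSVs a real study would
keep.  The image path (render → register → quantify) runs on one compact ROI;
the cohort path (gate → cluster → spatial → stats) runs on a multi-ROI,
multi-stage table cohort.  Everything is driven by a single seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from mihckit import fixtures, gating, registration, spatial, ssc, stain_quant
from mihckit.fixtures import MARKER_PANEL, STAGES
from mihckit.registration import SimilarityTransform
from mihckit.stats_report import pairwise_mwu_bonferroni, render_report


def run_image_roi(
    seed: int,
    out_dir: Path | None = None,
    n_cells: int = 100,
    roi_um: float = 130.0,
) -> dict:
    """Render one ROI with a planted round distortion and recover its cells.

    Returns the quantified cell table along with registration and
    segmentation accuracy metrics against the generator's ground truth.
    """
    rng = np.random.default_rng(seed)
    archetypes = fixtures.default_archetypes()
    per = n_cells // 3
    table = fixtures.synth_cell_table(
        archetypes,
        {"CD8+ T cells": per, "B cells": per,
         "Epithelial cells": n_cells - 2 * per},
        noise_seed=int(rng.integers(2**31)),
        roi_id="IMG_1",
    )
    scene = fixtures.synth_tissue_layout(
        table, "random", (roi_um, roi_um), seed=int(rng.integers(2**31)),
        min_spacing_um=10.0,
    )
    planted = SimilarityTransform(
        scale=1.02, angle=np.radians(3.0), translation=(10.0, -5.0)
    )
    transforms = [SimilarityTransform() for _ in range(len(MARKER_PANEL) + 1)]
    transforms[2] = planted
    rounds, truth = fixtures.render_round_images(
        scene, round_transforms=transforms, seed=int(rng.integers(2**31))
    )
    stack = registration.register_stack(rounds, reference_round=0)
    stain_quant.deconvolve_stack(stack, list(MARKER_PANEL))
    mask = stain_quant.segment_nuclei(stack.nuclear, stack.pixel_size_um)
    cells = stain_quant.quantify_cells(mask, stack)

    # registration accuracy at the crop corners
    est = stack.transforms[2]
    r0, r1, c0, c1 = stack.crop_box
    corners = np.array([[c0, r0], [c1, r0], [c0, r1], [c1, r1]], float)
    corner_err = float(
        np.linalg.norm(
            est.apply(planted.inverse().apply(corners)) - corners, axis=1
        ).max()
    )

    # segmentation recall: truth centroids matched within 1 px
    from scipy import ndimage as ndi

    ids_t = sorted(set(np.unique(truth.labels)) - {0})
    com_t = np.array(
        ndi.center_of_mass(np.ones_like(truth.labels), truth.labels, ids_t)
    )
    # only nuclei fully inside the common crop are recoverable
    margin = 1.2 * 3.8 / stack.pixel_size_um  # max nucleus radius in px
    inside = (
        (com_t[:, 0] >= r0 + margin) & (com_t[:, 0] <= r1 - margin)
        & (com_t[:, 1] >= c0 + margin) & (com_t[:, 1] <= c1 - margin)
    )
    com_t = com_t[inside]
    recall = 0.0
    if mask.n_cells:
        ids_f = sorted(mask.cell_ids)
        com_f = np.array(
            ndi.center_of_mass(np.ones_like(mask.labels), mask.labels, ids_f)
        )
        com_f = com_f + np.array([r0, c0])  # mask lives in the cropped frame
        d = np.linalg.norm(com_t[:, None] - com_f[None], axis=2)
        recall = float(np.mean(d.min(axis=1) <= 1.0))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cells.to_csv(out_dir / "image_roi_cells.csv", index=False)
        stack.save_transforms(out_dir / "image_roi_transforms.json")
    return {
        "cells": cells,
        "truth": scene.cells,
        "registration_corner_error_px": corner_err,
        "segmentation_recall": recall,
        "n_true": int(inside.sum()),
        "n_found": mask.n_cells,
    }


def run_pipeline(
    seed: int,
    out_dir: str | Path,
    rois_per_stage: int = 2,
    cells_per_roi: int = 350,
    roi_size: tuple[float, float] = (400.0, 400.0),
    n_perm: int = 1000,
    ssc_k: int | None = None,
    n_landmarks: int = 200,
    include_image_roi: bool = True,
) -> dict:
    """Full synthetic-cohort analysis; returns headline metrics and paths.

    Writes ``cells_labeled.csv``, ``summaries.csv``, ``comparisons.csv``,
    ``ssc_labels.csv``, ``cluster_profiles.csv``, ``enrichment.csv``,
    ``enrichment_by_stage.csv`` and the figure bundle under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics: dict = {}

    if include_image_roi:
        img = run_image_roi(seed + 1, out)
        metrics["registration_corner_error_px"] = img[
            "registration_corner_error_px"
        ]
        metrics["segmentation_recall"] = img["segmentation_recall"]

    # ---- cohort: simulate and gate -------------------------------------
    scenes = fixtures.synth_cohort(
        seed + 2, rois_per_stage=rois_per_stage, cells_per_roi=cells_per_roi,
        roi_size=roi_size,
    )
    tree = gating.default_gating_tree()
    tables = []
    for sc in scenes:
        t = sc.cells.copy()
        t["stage"] = sc.stage
        t["phenotype"] = gating.apply_gating_tree(t, tree)
        tables.append(t)
    cells = pd.concat(tables, ignore_index=True)
    cells.to_csv(out / "cells_labeled.csv", index=False)
    stage_by_roi = {sc.roi_id: sc.stage for sc in scenes}
    area = scenes[0].area_mm2

    summaries = gating.summarize_density_proportion(
        cells,
        roi_area_mm2={sc.roi_id: sc.area_mm2 for sc in scenes},
        denominators={
            "CD163+ myelomonocytic cells": "Myelomonocytic cells",
            "CD8+ T cells": "T cells",
        },
        tree=tree,
        stage_by_roi=stage_by_roi,
    )

    # ---- stage comparisons ---------------------------------------------
    comparisons = []
    for pop in ("T regulatory cells", "CD163+ myelomonocytic cells", "B cells"):
        vals = {
            s: summaries.loc[
                (summaries.stage == s) & (summaries.phenotype == pop),
                "density_per_mm2",
            ].to_numpy()
            for s in STAGES
        }
        comparisons.append(
            pairwise_mwu_bonferroni(
                vals, pairs=[("NSQ", "NDBE"), ("Dys", "EAC"), ("NSQ", "EAC")],
                population=pop,
            )
        )
    comparisons = pd.concat(comparisons, ignore_index=True)

    # ---- SSC on the pooled immune compartment --------------------------
    immune = ssc.filter_immune(cells)
    k = ssc_k if ssc_k is not None else immune["true_label"].nunique()
    model = ssc.fit_ssc(
        immune, k=k, n_landmarks=min(n_landmarks, len(immune)), seed=seed + 3
    )
    pd.DataFrame({"cell_id": model.cell_ids, "group": model.labels}).to_csv(
        out / "ssc_labels.csv", index=False
    )
    profiles = ssc.cluster_profiles(model.labels, immune)
    profiles.to_csv(out / "cluster_profiles.csv")
    gate_labels = immune["phenotype"].to_numpy()
    from sklearn.metrics import adjusted_rand_score

    metrics["ssc_gating_ari"] = float(
        adjusted_rand_score(gate_labels, model.labels)
    )
    metrics["n_immune"] = int(len(immune))

    # ---- spatial statistics --------------------------------------------
    phenos = sorted(cells["phenotype"].unique())
    results = []
    for sc in scenes:
        sub = cells[cells.roi_id == sc.roi_id].reset_index(drop=True)
        graph = spatial.knn_graph(sub, k=10, roi_id=sc.roi_id)
        results.append(
            spatial.neighborhood_enrichment(
                graph, sub["phenotype"].to_numpy(), n_perm=n_perm,
                seed=seed + 4, phenotypes=phenos,
            )
        )
    enrichment = pd.concat(results, ignore_index=True)
    enrichment.to_csv(out / "enrichment.csv", index=False)
    agg = spatial.aggregate_enrichment(enrichment, stage_by_roi)
    agg.to_csv(out / "enrichment_by_stage.csv", index=False)

    render_report(summaries, comparisons, agg, profiles, out_dir=out / "report")

    # headline biology of the synthetic cohort: Treg density by stage
    treg = summaries[summaries.phenotype == "T regulatory cells"]
    for s in STAGES:
        metrics[f"treg_density_{s}"] = float(
            treg.loc[treg.stage == s, "density_per_mm2"].mean()
        )
    metrics["area_mm2"] = float(area)
    metrics["n_cells"] = int(len(cells))
    return metrics
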