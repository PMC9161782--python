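"""Synthetic mIHC data with full ground truth.

No public single-cell mIHC dataset accompanies this pipeline, so every
downstream stage is exercised on synthetic fixtures generated here: single-cell
intensity tables drawn from phenotype archetypes (marker-sign combinations of
the esophageal immune panel), spatial layouts (uniform, clustered, two-block,
epithelium/margin), and rendered multi-round brightfield rasters in which
nuclei are hematoxylin-stained ellipses and each marker round overlays AEC
chromogen proportional to the cell's expression, distorted by a known
similarity transform per round.

Intensities live on a fixed [0, 1] scale so that the CD45 > 0.07 pan-immune
cut-off used throughout the toolkit is directly meaningful.  Noise is
multiplicative lognormal on per-cell intensities (positive-valued, unit mean)
and additive Gaussian on rendered pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Point, Polygon, box
from skimage import transform as sktransform
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from mihckit.registration import RoundImage, SimilarityTransform
from mihckit.stain_quant import (
    AEC_OD,
    DEFAULT_BACKGROUND,
    HEMATOXYLIN_OD,
    NucleusMask,
    _unit,
)

#: The 10-marker esophageal immune panel, in staining-round order.
MARKER_PANEL = (
    "CD45",
    "CD3",
    "CD8",
    "FOXP3",
    "CD20",
    "CD68",
    "CSF1R",
    "CD163",
    "CD1C",
    "KI67",
)

#: Disease-progression stages: normal squamous epithelium, non-dysplastic
#: Barrett's esophagus, dysplasia, esophageal adenocarcinoma.
STAGES = ("NSQ", "NDBE", "Dys", "EAC")

LAYOUTS = ("random", "clustered", "two_block", "epithelium_margin")


@dataclass(frozen=True)
class PhenotypeArchetype:
    """A phenotype as a marker-sign combination with intensity levels.

    ``marker_signs`` maps every panel marker to "+" or "-"; positive markers
    are sampled around ``mean_high`` and negative markers around ``mean_low``
    (both on the [0, 1] intensity scale) with multiplicative lognormal noise
    of scale ``dispersion``.
    """

    label: str
    marker_signs: dict[str, str]
    mean_high: float = 0.5
    mean_low: float = 0.03
    dispersion: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.mean_low < self.mean_high:
            raise ValueError("require mean_high > mean_low >= 0")
        for marker, sign in self.marker_signs.items():
            if sign not in ("+", "-"):
                raise ValueError(f"sign for {marker} must be '+' or '-'")

    def positive_markers(self) -> list[str]:
        return [m for m, s in self.marker_signs.items() if s == "+"]


def _signs(positive: str) -> dict[str, str]:
    pos = set(positive.split()) if positive else set()
    unknown = pos - set(MARKER_PANEL)
    if unknown:
        raise ValueError(f"unknown markers {sorted(unknown)}")
    return {m: ("+" if m in pos else "-") for m in MARKER_PANEL}


def default_archetypes(
    mean_high: float = 0.5, mean_low: float = 0.03, dispersion: float = 0.25
) -> list[PhenotypeArchetype]:
    """Archetypes for the terminal phenotypes of the default gating tree.

    One archetype per leaf population (lymphoid and myeloid lineages defined
    by their canonical marker combinations) plus a CD45-negative epithelial
    archetype.
    """
    combos = [
        ("Epithelial cells", ""),
        ("CD8+ T cells", "CD45 CD3 CD8"),
        ("Proliferating CD8 T cells", "CD45 CD3 CD8 KI67"),
        ("T regulatory cells", "CD45 CD3 FOXP3"),
        ("Proliferating T reg cells", "CD45 CD3 FOXP3 KI67"),
        ("Other Th cells", "CD45 CD3"),
        ("B cells", "CD45 CD20"),
        ("CD1C+ myeloid dendritic cells", "CD45 CD1C"),
        ("CD163+ myelomonocytic cells", "CD45 CD68 CSF1R CD163"),
        ("CD163- myelomonocytic cells", "CD45 CD68 CSF1R"),
        ("Monocytes, macrophages, fibrocytes", "CD45 CD68"),
    ]
    return [
        PhenotypeArchetype(label, _signs(pos), mean_high, mean_low, dispersion)
        for label, pos in combos
    ]


#: Stage-dependent phenotype composition (fractions, renormalised at draw
#: time).  Immune infiltration rises with progression, with steadily
#: increasing T-regulatory and CD163+ myelomonocytic fractions.
STAGE_COMPOSITION: dict[str, dict[str, float]] = {
    "NSQ": {
        "Epithelial cells": 0.70,
        "CD8+ T cells": 0.080,
        "Proliferating CD8 T cells": 0.010,
        "T regulatory cells": 0.010,
        "Proliferating T reg cells": 0.003,
        "Other Th cells": 0.060,
        "B cells": 0.040,
        "CD1C+ myeloid dendritic cells": 0.020,
        "CD163+ myelomonocytic cells": 0.010,
        "CD163- myelomonocytic cells": 0.050,
        "Monocytes, macrophages, fibrocytes": 0.017,
    },
    "NDBE": {
        "Epithelial cells": 0.62,
        "CD8+ T cells": 0.070,
        "Proliferating CD8 T cells": 0.010,
        "T regulatory cells": 0.040,
        "Proliferating T reg cells": 0.005,
        "Other Th cells": 0.070,
        "B cells": 0.050,
        "CD1C+ myeloid dendritic cells": 0.020,
        "CD163+ myelomonocytic cells": 0.020,
        "CD163- myelomonocytic cells": 0.080,
        "Monocytes, macrophages, fibrocytes": 0.015,
    },
    "Dys": {
        "Epithelial cells": 0.56,
        "CD8+ T cells": 0.050,
        "Proliferating CD8 T cells": 0.010,
        "T regulatory cells": 0.050,
        "Proliferating T reg cells": 0.010,
        "Other Th cells": 0.080,
        "B cells": 0.050,
        "CD1C+ myeloid dendritic cells": 0.030,
        "CD163+ myelomonocytic cells": 0.080,
        "CD163- myelomonocytic cells": 0.050,
        "Monocytes, macrophages, fibrocytes": 0.020,
    },
    "EAC": {
        "Epithelial cells": 0.50,
        "CD8+ T cells": 0.040,
        "Proliferating CD8 T cells": 0.010,
        "T regulatory cells": 0.080,
        "Proliferating T reg cells": 0.010,
        "Other Th cells": 0.090,
        "B cells": 0.050,
        "CD1C+ myeloid dendritic cells": 0.040,
        "CD163+ myelomonocytic cells": 0.100,
        "CD163- myelomonocytic cells": 0.060,
        "Monocytes, macrophages, fibrocytes": 0.030,
    },
}


@dataclass
class SyntheticScene:
    """One synthetic ROI: a truth-labelled cell table with coordinates."""

    roi_id: str
    stage: str
    cells: pd.DataFrame  # cell_id, roi_id, markers..., true_label, x_um, y_um
    layout: str
    roi_size: tuple[float, float]  # (width, height) in µm
    epithelium: Polygon | None = None

    @property
    def area_mm2(self) -> float:
        return self.roi_size[0] * self.roi_size[1] / 1e6


def synth_cell_table(
    archetypes: list[PhenotypeArchetype],
    counts: dict[str, int],
    noise_seed: int,
    roi_id: str = "ROI_1",
) -> pd.DataFrame:
    """Draw a truth-labelled single-cell intensity table.

    Each requested cell's marker intensities are sampled around its
    archetype's ``mean_high`` ("+" markers) or ``mean_low`` ("-" markers)
    with unit-mean multiplicative lognormal noise, clipped to [0, 1].
    Reproducible for a fixed ``noise_seed``.
    """
    by_label = {}
    for a in archetypes:
        if a.label in by_label:
            raise ValueError(f"duplicate archetype label {a.label!r}")
        missing = set(MARKER_PANEL) - set(a.marker_signs)
        unknown = set(a.marker_signs) - set(MARKER_PANEL)
        if unknown:
            raise ValueError(f"archetype {a.label!r}: unknown markers {sorted(unknown)}")
        if missing:
            raise ValueError(f"archetype {a.label!r}: missing signs for {sorted(missing)}")
        by_label[a.label] = a

    columns = ["cell_id", "roi_id", *MARKER_PANEL, "true_label"]
    rng = np.random.default_rng(noise_seed)
    frames = []
    next_id = 1
    for label, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for {label!r}")
        if label not in by_label:
            raise ValueError(f"no archetype named {label!r}")
        if n == 0:
            continue
        a = by_label[label]
        data = {"cell_id": np.arange(next_id, next_id + n), "roi_id": roi_id}
        mu = -0.5 * a.dispersion**2  # unit-mean lognormal multiplier
        for marker in MARKER_PANEL:
            base = a.mean_high if a.marker_signs[marker] == "+" else a.mean_low
            mult = rng.lognormal(mean=mu, sigma=a.dispersion, size=n)
            data[marker] = np.clip(base * mult, 0.0, 1.0)
        data["true_label"] = label
        frames.append(pd.DataFrame(data, columns=columns))
        next_id += n
    if not frames:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in columns}).astype(
            {"roi_id": str, "true_label": str}
        )
    return pd.concat(frames, ignore_index=True)


def default_epithelium(roi_size: tuple[float, float], fraction: float = 0.4) -> Polygon:
    """Rectangular epithelial compartment spanning the left ``fraction`` of the ROI."""
    return box(0.0, 0.0, roi_size[0] * fraction, roi_size[1])


def _sample_in_region(
    rng: np.random.Generator,
    n: int,
    roi_size: tuple[float, float],
    region: Polygon,
    inside: bool,
    max_tries: int = 10000,
) -> np.ndarray:
    pts = np.empty((n, 2))
    got = 0
    tries = 0
    while got < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("rejection sampling failed; region too small?")
        batch = rng.uniform([0, 0], roi_size, size=(max(64, n), 2))
        for p in batch:
            ok = region.contains(Point(p))
            if ok == inside:
                pts[got] = p
                got += 1
                if got == n:
                    break
    return pts


def synth_tissue_layout(
    table: pd.DataFrame,
    layout: str,
    roi_size: tuple[float, float],
    seed: int,
    stage: str = "NSQ",
    epithelium: Polygon | None = None,
    focal_label: str | None = None,
    n_clumps: int = 3,
    clump_sd_um: float = 20.0,
    min_spacing_um: float | None = None,
) -> SyntheticScene:
    """Assign spatial coordinates (µm) to a cell table.

    Layouts: ``random`` (uniform; optionally with a minimum spacing by dart
    throwing), ``clustered`` (per-label Gaussian clumps), ``two_block`` (labels
    placed into disjoint left/right halves by order of appearance), and
    ``epithelium_margin`` (the focal label inside the epithelial region,
    everything else outside).
    """
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; choose from {LAYOUTS}")
    w, h = roi_size
    if w <= 0 or h <= 0:
        raise ValueError("roi_size must be positive")
    cells = table.copy()
    n = len(cells)
    rng = np.random.default_rng(seed)
    xy = np.zeros((n, 2))
    labels = (
        cells["true_label"].to_numpy()
        if "true_label" in cells
        else np.repeat("cell", n)
    )

    if layout == "random":
        if min_spacing_um is None:
            xy = rng.uniform([0, 0], [w, h], size=(n, 2))
        else:
            placed: list[np.ndarray] = []
            for _ in range(n):
                for _try in range(5000):
                    p = rng.uniform([0, 0], [w, h])
                    if not placed or np.min(
                        np.linalg.norm(np.array(placed) - p, axis=1)
                    ) >= min_spacing_um:
                        placed.append(p)
                        break
                else:
                    raise RuntimeError("could not honour min_spacing_um; too dense")
            xy = np.array(placed) if placed else xy
    elif layout == "clustered":
        for label in pd.unique(labels):
            idx = np.flatnonzero(labels == label)
            centers = rng.uniform([0, 0], [w, h], size=(n_clumps, 2))
            assign = rng.integers(0, n_clumps, size=len(idx))
            pts = centers[assign] + rng.normal(0, clump_sd_um, size=(len(idx), 2))
            xy[idx] = np.clip(pts, [0, 0], [w, h])
    elif layout == "two_block":
        for i, label in enumerate(pd.unique(labels)):
            idx = np.flatnonzero(labels == label)
            lo, hi = (0.0, w / 2) if i % 2 == 0 else (w / 2, w)
            xy[idx, 0] = rng.uniform(lo, hi, size=len(idx))
            xy[idx, 1] = rng.uniform(0, h, size=len(idx))
    else:  # epithelium_margin
        region = epithelium if epithelium is not None else default_epithelium(roi_size)
        if region.is_empty:
            raise ValueError("empty epithelium region")
        focal = focal_label if focal_label is not None else labels[0] if n else None
        for label in pd.unique(labels):
            idx = np.flatnonzero(labels == label)
            xy[idx] = _sample_in_region(
                rng, len(idx), roi_size, region, inside=(label == focal)
            )
        epithelium = region

    cells["x_um"] = xy[:, 0]
    cells["y_um"] = xy[:, 1]
    roi_id = str(cells["roi_id"].iloc[0]) if n else "ROI_1"
    return SyntheticScene(
        roi_id=roi_id,
        stage=stage,
        cells=cells,
        layout=layout,
        roi_size=(float(w), float(h)),
        epithelium=epithelium,
    )


def render_round_images(
    scene: SyntheticScene,
    pixel_size_um: float = 0.22,
    round_transforms: list[SimilarityTransform] | None = None,
    seed: int = 0,
    nucleus_radius_um: tuple[float, float] = (2.6, 3.8),
    hematoxylin_conc: float = 0.85,
    aec_radius_factor: float = 1.3,
    background: float = DEFAULT_BACKGROUND,
    noise_sd: float = 1.5,
    stroma_od: float = 0.18,
    stroma_scale_um: float = 3.0,
    touching: bool = False,
) -> tuple[list[RoundImage], NucleusMask]:
    """Render one brightfield RGB raster per staining round plus ground truth.

    Round 0 is the hematoxylin-only nuclear scan; rounds 1..10 add AEC
    chromogen over each cell with amplitude equal to the cell's intensity for
    that round's marker.  Nuclei are ellipses (hematoxylin Beer–Lambert
    absorbance); each round may be distorted by a known similarity transform
    (moving→reference convention, matching the registration module) and gets
    additive Gaussian pixel noise.  The ground-truth label mask is in the
    undistorted reference frame, with labels equal to cell ids.

    ``touching=True`` drags every second cell next to its predecessor so that
    nuclei overlap, to stress watershed splitting.
    """
    markers = [m for m in MARKER_PANEL if m in scene.cells.columns]
    n_rounds = len(markers) + 1
    if round_transforms is None:
        round_transforms = [SimilarityTransform() for _ in range(n_rounds)]
    if len(round_transforms) != n_rounds:
        raise ValueError(
            f"need {n_rounds} transforms (hematoxylin + {len(markers)} markers), "
            f"got {len(round_transforms)}"
        )

    rng = np.random.default_rng(seed)
    w_um, h_um = scene.roi_size
    H = int(round(h_um / pixel_size_um))
    W = int(round(w_um / pixel_size_um))
    cells = scene.cells
    n = len(cells)
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float) / pixel_size_um
    if touching and n > 1:
        for i in range(1, n, 2):
            direction = rng.normal(size=2)
            direction /= np.linalg.norm(direction)
            gap_px = 1.8 * nucleus_radius_um[0] / pixel_size_um
            xy[i] = np.clip(xy[i - 1] + direction * gap_px, 0, [W - 1, H - 1])

    radii = rng.uniform(*nucleus_radius_um, size=(n, 2)) / pixel_size_um
    angles = rng.uniform(0, np.pi, size=n)
    hem_jitter = rng.lognormal(-0.02, 0.08, size=n)

    truth = np.zeros((H, W), dtype=np.int32)
    hem_conc = np.zeros((H, W))
    cell_ids = cells["cell_id"].to_numpy() if n else np.array([], dtype=int)
    for i in range(n):
        rr, cc = draw_ellipse(
            xy[i, 1], xy[i, 0], radii[i, 0], radii[i, 1],
            rotation=angles[i], shape=(H, W),
        )
        free = truth[rr, cc] == 0
        truth[rr[free], cc[free]] = cell_ids[i]
        hem_conc[rr, cc] = np.maximum(
            hem_conc[rr, cc], hematoxylin_conc * hem_jitter[i]
        )

    v_hem = _unit(HEMATOXYLIN_OD)
    v_aec = _unit(AEC_OD)

    # stromal texture: a smooth random absorbance field along the hematoxylin
    # vector, identical in every round (it is the same tissue) — this is what
    # gives the feature matcher distinctive, non-repetitive gradients
    if stroma_od > 0:
        from scipy.ndimage import gaussian_filter

        tex = gaussian_filter(
            rng.standard_normal((H, W)), sigma=stroma_scale_um / pixel_size_um
        )
        tex -= tex.min()
        peak = tex.max()
        stroma = stroma_od * (tex / peak if peak > 0 else tex)
    else:
        stroma = np.zeros((H, W))

    def _compose(aec_conc: np.ndarray | None) -> np.ndarray:
        od = np.maximum(hem_conc, stroma)[..., None] * v_hem
        if aec_conc is not None:
            od = od + aec_conc[..., None] * v_aec
        return background * np.exp(-od)

    rounds: list[RoundImage] = []
    for r in range(n_rounds):
        if r == 0:
            rgb = _compose(None)
        else:
            marker = markers[r - 1]
            intensity = cells[marker].to_numpy(dtype=float)
            aec_conc = np.zeros((H, W))
            mean_rad = radii.mean(axis=1) * aec_radius_factor
            for i in range(n):
                rr, cc = draw_disk((xy[i, 1], xy[i, 0]), mean_rad[i], shape=(H, W))
                aec_conc[rr, cc] = np.maximum(aec_conc[rr, cc], intensity[i])
            rgb = _compose(aec_conc)

        t = round_transforms[r]
        if not (
            np.isclose(t.scale, 1) and np.isclose(t.angle, 0)
            and np.allclose(t.translation, 0)
        ):
            warped = np.stack(
                [
                    sktransform.warp(
                        rgb[..., c], t.to_skimage(), output_shape=(H, W),
                        order=1, cval=background, preserve_range=True,
                    )
                    for c in range(3)
                ],
                axis=-1,
            )
            rgb = warped
        rgb = rgb + rng.normal(0, noise_sd, size=rgb.shape)
        rounds.append(
            RoundImage(
                roi_id=scene.roi_id,
                round_index=r,
                rgb=np.clip(rgb, 0, 255).astype(np.uint8),
                pixel_size_um=pixel_size_um,
            )
        )
    return rounds, NucleusMask(truth)


def synth_cohort(
    seed: int,
    rois_per_stage: int = 2,
    cells_per_roi: int = 400,
    roi_size: tuple[float, float] = (400.0, 400.0),
    layout: str = "clustered",
    archetypes: list[PhenotypeArchetype] | None = None,
) -> list[SyntheticScene]:
    """Generate a multi-stage cohort of ROIs with stage-dependent composition."""
    archetypes = archetypes if archetypes is not None else default_archetypes()
    labels = [a.label for a in archetypes]
    rng = np.random.default_rng(seed)
    scenes = []
    for stage in STAGES:
        weights = np.array([STAGE_COMPOSITION[stage].get(l, 0.0) for l in labels])
        weights = weights / weights.sum()
        for j in range(rois_per_stage):
            roi_id = f"{stage}_{j + 1}"
            draw = rng.multinomial(cells_per_roi, weights)
            counts = {l: int(c) for l, c in zip(labels, draw) if c > 0}
            table = synth_cell_table(
                archetypes, counts, noise_seed=int(rng.integers(2**31)), roi_id=roi_id
            )
            scene = synth_tissue_layout(
                table, layout, roi_size, seed=int(rng.integers(2**31)), stage=stage
            )
            scenes.append(scene)
    return scenes


def save_scene(
    scene: SyntheticScene,
    out_dir: str | Path,
    rounds: list[RoundImage] | None = None,
    truth: NucleusMask | None = None,
) -> None:
    """Write a scene to disk: cell CSV, YAML descriptor, optional TIFFs."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene.cells.to_csv(out / f"{scene.roi_id}_cells.csv", index=False)
    desc = {
        "roi_id": scene.roi_id,
        "stage": scene.stage,
        "layout": scene.layout,
        "roi_size_um": list(scene.roi_size),
        "n_cells": int(len(scene.cells)),
    }
    (out / f"{scene.roi_id}_scene.yaml").write_text(yaml.safe_dump(desc))
    if rounds is not None:
        for r in rounds:
            tifffile.imwrite(
                out / f"{scene.roi_id}_round{r.round_index:02d}.tif", r.rgb
            )
    if truth is not None:
        tifffile.imwrite(
            out / f"{scene.roi_id}_truth_mask.tif", truth.labels.astype(np.uint16)
        )
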