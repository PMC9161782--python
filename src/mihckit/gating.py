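"""Config-driven hierarchical gating, spatial gates, and density summaries.

Replaces interactive image-cytometry gating with a deterministic engine: each
marker's positivity is a strict ``intensity > threshold`` test, and an ordered
list of marker-sign conjunction rules is evaluated first-match-wins, so every
cell receives exactly one phenotype label (catch-all pan-immune and non-immune
rules close the partition).  Spatial gating keeps cells inside an annotated
epithelial region or within a stromal margin (default 200 µm) of its boundary.
Summaries report per-ROI cell densities (cells/mm²) and proportions within a
stated denominator population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi
from shapely import contains_xy
from shapely.geometry import Polygon

from mihckit.fixtures import MARKER_PANEL


@dataclass
class GatingTree:
    """Ordered marker-sign rules plus per-marker positivity thresholds.

    ``rules`` is a list of ``(label, signs)`` where ``signs`` maps markers to
    "+" or "-"; a rule with an empty sign map matches everything and acts as
    the catch-all.  ``groups`` optionally names composite populations as
    unions of rule labels, used by the density/proportion summary.
    """

    rules: list[tuple[str, dict[str, str]]]
    thresholds: dict[str, float]
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("gating tree needs at least one rule")
        for label, signs in self.rules:
            for marker, sign in signs.items():
                if sign not in ("+", "-"):
                    raise ValueError(f"rule {label!r}: sign must be '+' or '-'")
                if marker not in self.thresholds:
                    raise ValueError(
                        f"rule {label!r} references marker {marker!r} "
                        "with no threshold"
                    )
        last_signs = self.rules[-1][1]
        if last_signs:
            raise ValueError(
                "last rule must be a catch-all (empty sign map) so the rule "
                "list partitions the sign space"
            )

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.rules]

    def classify_signs(self, signs: dict[str, bool]) -> str:
        """Label a single boolean sign vector (first full match wins)."""
        for label, rule in self.rules:
            if all(signs[m] == (s == "+") for m, s in rule.items()):
                return label
        raise AssertionError("unreachable: catch-all rule guarantees a match")

    def population_members(self, population: str) -> list[str]:
        """Terminal labels making up ``population`` (itself if terminal)."""
        if population in self.groups:
            return list(self.groups[population])
        if population in self.labels:
            return [population]
        raise KeyError(f"unknown population {population!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GatingTree":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(
            rules=[(r["label"], dict(r.get("signs") or {})) for r in cfg["rules"]],
            thresholds={str(k): float(v) for k, v in cfg["thresholds"].items()},
            groups={k: list(v) for k, v in (cfg.get("groups") or {}).items()},
        )

    def to_yaml(self, path: str | Path) -> None:
        cfg = {
            "thresholds": self.thresholds,
            "rules": [{"label": l, "signs": s} for l, s in self.rules],
            "groups": self.groups,
        }
        Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def default_gating_tree() -> GatingTree:
    """The shipped gating configuration for the 10-marker panel."""
    with resources.as_file(
        resources.files("mihckit").joinpath("data/default_gates.yaml")
    ) as p:
        return GatingTree.from_yaml(p)


def apply_gating_tree(cells: pd.DataFrame, tree: GatingTree) -> pd.Series:
    """Assign one phenotype label per cell.

    Positivity is strict: ``intensity > threshold``.  Rules are evaluated in
    order and the first full conjunction match wins.
    """
    used = {m for _, signs in tree.rules for m in signs}
    missing = used - set(cells.columns)
    if missing:
        raise KeyError(f"cell table lacks marker columns {sorted(missing)}")

    pos = {
        m: cells[m].to_numpy(dtype=float) > tree.thresholds[m] for m in used
    }
    n = len(cells)
    out = np.empty(n, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for label, signs in tree.rules:
        if not signs:
            out[unassigned] = label
            unassigned[:] = False
            break
        match = unassigned.copy()
        for m, s in signs.items():
            match &= pos[m] if s == "+" else ~pos[m]
        out[match] = label
        unassigned &= ~match
    return pd.Series(out, index=cells.index, name="phenotype")


def _region_to_mask(
    region: Polygon | np.ndarray,
    bounds: tuple[float, float, float, float],
    resolution_um: float,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Rasterize a region over ``bounds`` = (xmin, ymin, xmax, ymax)."""
    xmin, ymin, xmax, ymax = bounds
    W = max(1, int(math.ceil((xmax - xmin) / resolution_um)) + 1)
    H = max(1, int(math.ceil((ymax - ymin) / resolution_um)) + 1)
    if isinstance(region, np.ndarray):
        # binary mask already sampled at resolution_um with origin (0, 0)
        mask = np.zeros((H, W), dtype=bool)
        src = region.astype(bool)
        r_off = int(round(-ymin / resolution_um))
        c_off = int(round(-xmin / resolution_um))
        r0, c0 = max(0, r_off), max(0, c_off)
        r1 = min(H, r_off + src.shape[0])
        c1 = min(W, c_off + src.shape[1])
        mask[r0:r1, c0:c1] = src[r0 - r_off : r1 - r_off, c0 - c_off : c1 - c_off]
        return mask, (xmin, ymin)
    xs = xmin + np.arange(W) * resolution_um
    ys = ymin + np.arange(H) * resolution_um
    gx, gy = np.meshgrid(xs, ys)
    mask = contains_xy(region.buffer(resolution_um / 2), gx, gy)
    return mask, (xmin, ymin)


def spatial_gate(
    cells: pd.DataFrame,
    region: Polygon | np.ndarray,
    margin_um: float = 200.0,
    resolution_um: float = 1.0,
) -> pd.DataFrame:
    """Keep cells inside the region or within ``margin_um`` of its boundary.

    The region (polygon in µm coordinates, or a binary mask sampled at
    ``resolution_um``) is rasterized and the Euclidean distance to it computed
    by distance transform, so arbitrary shapes are handled uniformly.
    """
    if margin_um < 0:
        raise ValueError("margin_um must be non-negative")
    if isinstance(region, Polygon):
        if region.is_empty:
            raise ValueError("empty region")
        rb = region.bounds
    else:
        if not np.any(region):
            raise ValueError("empty region")
        rb = (0.0, 0.0, region.shape[1] * resolution_um, region.shape[0] * resolution_um)
    if len(cells) == 0:
        return cells.copy()

    x = cells["x_um"].to_numpy(dtype=float)
    y = cells["y_um"].to_numpy(dtype=float)
    pad = margin_um + 2 * resolution_um
    bounds = (
        min(rb[0], x.min()) - pad,
        min(rb[1], y.min()) - pad,
        max(rb[2], x.max()) + pad,
        max(rb[3], y.max()) + pad,
    )
    mask, (ox, oy) = _region_to_mask(region, bounds, resolution_um)
    dist = ndi.distance_transform_edt(~mask, sampling=resolution_um)
    rows = np.clip(np.round((y - oy) / resolution_um).astype(int), 0, mask.shape[0] - 1)
    cols = np.clip(np.round((x - ox) / resolution_um).astype(int), 0, mask.shape[1] - 1)
    keep = dist[rows, cols] <= margin_um
    return cells.loc[keep].copy()


def summarize_density_proportion(
    labeled_cells: pd.DataFrame,
    roi_area_mm2: float | dict[str, float],
    denominators: dict[str, str] | None = None,
    tree: GatingTree | None = None,
    stage_by_roi: dict[str, str] | None = None,
    label_col: str = "phenotype",
) -> pd.DataFrame:
    """Per-ROI phenotype counts, densities (cells/mm²) and proportions.

    ``denominators`` maps a population to the population used as its
    proportion denominator (e.g. CD163+ myelomonocytic cells within total
    myelomonocytic cells); composite populations are resolved through the
    gating tree's groups.  A zero denominator flags the proportion undefined
    (NaN) rather than raising.
    """
    denominators = denominators or {}
    if label_col not in labeled_cells.columns:
        raise KeyError(f"missing {label_col!r} column")
    rois = list(pd.unique(labeled_cells["roi_id"]))
    if isinstance(roi_area_mm2, dict):
        areas = roi_area_mm2
    else:
        if roi_area_mm2 <= 0:
            raise ValueError("roi area must be positive")
        areas = {r: float(roi_area_mm2) for r in rois}

    def members(pop: str) -> list[str]:
        if tree is not None:
            return tree.population_members(pop)
        return [pop]

    populations = list(pd.unique(labeled_cells[label_col]))
    for pop in denominators:
        if pop not in populations:
            populations.append(pop)
    records = []
    for roi in rois:
        sub = labeled_cells[labeled_cells["roi_id"] == roi]
        area = areas[roi]
        if area <= 0:
            raise ValueError(f"roi {roi!r}: area must be positive")
        counts = sub[label_col].value_counts()

        def pop_count(pop: str) -> int:
            return int(sum(counts.get(m, 0) for m in members(pop)))

        for pop in populations:
            c = pop_count(pop)
            rec = {
                "roi_id": roi,
                "stage": (stage_by_roi or {}).get(roi, ""),
                "phenotype": pop,
                "count": c,
                "density_per_mm2": c / area,
                "proportion": np.nan,
                "proportion_defined": False,
            }
            if pop in denominators:
                denom = pop_count(denominators[pop])
                if denom > 0:
                    rec["proportion"] = c / denom
                    rec["proportion_defined"] = True
            records.append(rec)
    return pd.DataFrame.from_records(records)


def biaxial_pair_count(panel_size: int) -> int:
    """Number of distinct biaxial (two-marker) plots needed for a panel.

    Counted by explicit enumeration of unordered marker pairs: manual gating
    inspects every pair of markers once, so a 10-marker panel needs 45 plots.
    """
    if panel_size < 2:
        raise ValueError("panel_size must be at least 2")
    return sum(1 for _ in combinations(range(panel_size), 2))


PANEL_SIZE = len(MARKER_PANEL)
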