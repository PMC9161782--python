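"""Spatial proximity and neighborhood-enrichment statistics between phenotypes.

Two complementary views of tissue organization:

* **Shortest distances** — for every reference-phenotype cell, the Euclidean
  distance (µm, nucleus center to nucleus center) to its nearest target-
  phenotype cell, summarized as a mean and as fractions within proximity
  thresholds (30 and 50 µm by default).

* **Neighborhood enrichment** — each cell's k nearest neighbors (k = 10 by
  default) define a spatial graph; the observed mean number of target-type
  neighbors around reference-type cells is compared with a null built by
  shuffling phenotype labels over the fixed coordinates (1,000 permutations
  by default).  Pairs are classed enriched / depleted / non-significant by an
  empirical two-sided p-value with the +1 permutation correction.  Results
  are directional: enrichment of B around A need not equal that of A around B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass
class SpatialGraph:
    """Per-ROI knn graph: ``neighbors[i]`` are the k nearest cells to cell i."""

    roi_id: str
    neighbors: np.ndarray  # (N, k_eff) int indices
    distances: np.ndarray  # (N, k_eff) µm
    k: int

    @property
    def n_cells(self) -> int:
        return self.neighbors.shape[0]


@dataclass
class DistanceResult:
    """Nearest-target distances per reference cell; ``defined`` is False when
    either phenotype set is empty (or self-distances are requested of a
    singleton), in which case ``mean_um`` is NaN rather than 0."""

    reference: str
    target: str
    distances_um: np.ndarray
    defined: bool

    @property
    def mean_um(self) -> float:
        return float(np.mean(self.distances_um)) if self.defined else float("nan")


def knn_graph(cells: pd.DataFrame, k: int = 10, roi_id: str | None = None) -> SpatialGraph:
    """Build the k-nearest-neighbor graph on centroid coordinates (µm).

    Self-edges are excluded; each cell gets exactly ``min(k, N-1)`` neighbors.
    Ties at the kth distance are broken by cell index for determinism.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    n = len(xy)
    if n < 2:
        raise ValueError("need at least 2 cells for a knn graph")
    k_eff = min(k, n - 1)
    tree = cKDTree(xy)
    dist, idx = tree.query(xy, k=k_eff + 1)
    neighbors = np.empty((n, k_eff), dtype=int)
    distances = np.empty((n, k_eff))
    for i in range(n):
        row_d, row_i = dist[i], idx[i]
        keep = row_i != i
        row_d, row_i = row_d[keep][:k_eff], row_i[keep][:k_eff]
        order = np.lexsort((row_i, row_d))  # distance, then index
        neighbors[i] = row_i[order]
        distances[i] = row_d[order]
    rid = roi_id or (str(cells["roi_id"].iloc[0]) if "roi_id" in cells else "ROI")
    return SpatialGraph(roi_id=rid, neighbors=neighbors, distances=distances, k=k)


def mean_shortest_distance(
    cells: pd.DataFrame,
    reference: str,
    target: str,
    label_col: str = "phenotype",
) -> DistanceResult:
    """Mean distance from each reference cell to its nearest target cell.

    When reference and target phenotypes coincide the cell itself is excluded,
    so a singleton self-comparison is flagged undefined.
    """
    labels = cells[label_col].to_numpy()
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    ref_xy = xy[labels == reference]
    tgt_xy = xy[labels == target]
    if len(ref_xy) == 0 or len(tgt_xy) == 0:
        return DistanceResult(reference, target, np.array([]), defined=False)
    if reference == target:
        if len(ref_xy) < 2:
            return DistanceResult(reference, target, np.array([]), defined=False)
        tree = cKDTree(tgt_xy)
        d, _ = tree.query(ref_xy, k=2)
        return DistanceResult(reference, target, d[:, 1], defined=True)
    tree = cKDTree(tgt_xy)
    d, _ = tree.query(ref_xy, k=1)
    return DistanceResult(reference, target, np.atleast_1d(d), defined=True)


def proximity_fractions(
    distances_um: np.ndarray, thresholds_um: tuple[float, ...] = (30.0, 50.0)
) -> dict[float, float]:
    """Fraction of reference cells whose nearest target lies within each threshold."""
    d = np.asarray(distances_um, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance vector")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return {float(t): float(np.mean(d <= t)) for t in thresholds_um}


def _pair_stats(
    neighbors: np.ndarray, labels: np.ndarray, phenotypes: list
) -> np.ndarray:
    """Observed statistic matrix: mean target-neighbor count per reference cell."""
    P = len(phenotypes)
    code = {p: i for i, p in enumerate(phenotypes)}
    coded = np.array([code[l] for l in labels])
    neigh = coded[neighbors]  # (N, k)
    counts = np.stack([(neigh == t).sum(axis=1) for t in range(P)], axis=1)  # N x P
    stats = np.full((P, P), np.nan)
    for r in range(P):
        mask = coded == r
        if mask.any():
            stats[r] = counts[mask].mean(axis=0)
    return stats


def neighborhood_enrichment(
    graph: SpatialGraph,
    labels: np.ndarray | pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    phenotypes: list | None = None,
) -> pd.DataFrame:
    """Permutation test for phenotype-pair enrichment in knn neighborhoods.

    The observed statistic for a (reference, target) pair is the mean number
    of target-labelled neighbors over reference-labelled cells.  The null
    distribution shuffles the label vector over the fixed graph ``n_perm``
    times with a seeded generator; ``z = (obs - mean_perm) / sd_perm`` and the
    empirical two-sided p is ``(#{|perm - mean| >= |obs - mean|} + 1) /
    (n_perm + 1)``.  Pairs involving a phenotype absent from the ROI are
    flagged not evaluable.  No multiple-testing correction is applied at this
    stage (matching common neighborhood-analysis practice); correct downstream
    if desired.
    """
    labels = np.asarray(labels)
    if len(labels) != graph.n_cells:
        raise ValueError("labels must cover all graph nodes")
    present = sorted(set(labels.tolist()))
    phenotypes = list(phenotypes) if phenotypes is not None else present
    P = len(phenotypes)
    present_set = set(present)

    eval_idx = [i for i, p in enumerate(phenotypes) if p in present_set]
    eval_phen = [phenotypes[i] for i in eval_idx]
    obs_full = np.full((P, P), np.nan)
    obs_eval = _pair_stats(graph.neighbors, labels, eval_phen)
    for a, i in enumerate(eval_idx):
        for b, j in enumerate(eval_idx):
            obs_full[i, j] = obs_eval[a, b]

    rng = np.random.default_rng(seed)
    perm_stats = np.empty((n_perm, len(eval_idx), len(eval_idx)))
    for p in range(n_perm):
        perm = rng.permutation(labels)
        perm_stats[p] = _pair_stats(graph.neighbors, perm, eval_phen)

    perm_mean = np.nanmean(perm_stats, axis=0)
    perm_sd = np.nanstd(perm_stats, axis=0)
    centered = np.abs(perm_stats - perm_mean[None])
    obs_dev = np.abs(obs_eval - perm_mean)
    with np.errstate(invalid="ignore"):
        exceed = np.nansum(centered >= obs_dev[None] - 1e-12, axis=0)
    pvals = (exceed + 1) / (n_perm + 1)

    records = []
    for i, ref in enumerate(phenotypes):
        for j, tgt in enumerate(phenotypes):
            if ref not in present_set or tgt not in present_set:
                records.append(
                    {
                        "roi_id": graph.roi_id, "reference": ref, "target": tgt,
                        "observed": np.nan, "perm_mean": np.nan, "perm_sd": np.nan,
                        "z": np.nan, "p": np.nan, "class": "not_evaluable",
                        "evaluable": False,
                    }
                )
                continue
            a, b = eval_idx.index(i), eval_idx.index(j)
            obs = obs_eval[a, b]
            mu, sd = perm_mean[a, b], perm_sd[a, b]
            z = 0.0 if sd < 1e-12 else (obs - mu) / sd
            pv = float(pvals[a, b])
            if pv < alpha and obs > mu:
                cls = "enriched"
            elif pv < alpha and obs < mu:
                cls = "depleted"
            else:
                cls = "ns"
            records.append(
                {
                    "roi_id": graph.roi_id, "reference": ref, "target": tgt,
                    "observed": float(obs), "perm_mean": float(mu),
                    "perm_sd": float(sd), "z": float(z), "p": pv, "class": cls,
                    "evaluable": True,
                }
            )
    return pd.DataFrame.from_records(records)


def aggregate_enrichment(
    results: pd.DataFrame | list[pd.DataFrame],
    stage_by_roi: dict[str, str],
) -> pd.DataFrame:
    """Stage-level mean z per phenotype pair across ROIs.

    Not-evaluable entries are skipped; the number of contributing ROIs is
    attached per pair.  A stage with zero ROIs is an error.
    """
    if isinstance(results, list):
        results = pd.concat(results, ignore_index=True)
    df = results.copy()
    df["stage"] = df["roi_id"].map(stage_by_roi)
    if df["stage"].isna().any():
        missing = sorted(df.loc[df["stage"].isna(), "roi_id"].unique())
        raise ValueError(f"no stage for ROIs {missing}")
    stages = set(stage_by_roi.values())
    present = set(df["stage"].unique())
    empty = stages - present
    if empty:
        raise ValueError(f"stages with zero ROIs: {sorted(empty)}")
    ev = df[df["evaluable"]]
    agg = (
        ev.groupby(["stage", "reference", "target"])
        .agg(mean_z=("z", "mean"), n_roi=("roi_id", "nunique"))
        .reset_index()
    )
    return agg
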