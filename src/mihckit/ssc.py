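"""Automated cell phenotyping by landmark sparse subspace clustering (SSC).

SSC exploits the self-expressiveness of data lying on a union of low-
dimensional subspaces: each cell's 10-marker expression vector ``x_i`` can be
written as a linear combination ``x_i = X c_i`` of other cells, with the
self-coefficient constrained to zero, and among all representations a sparse
one (minimal l1 norm) selects coefficients concentrated on cells from the
same subspace.  For tractability at cohort scale, coding is done against a
reduced dictionary of representative landmark cells; the sparse coefficients
define a non-negative symmetric affinity whose spectral clustering yields the
cell groups.

The practical solver is the noise-tolerant Lasso relaxation
``min 1/2 ||x_i - D c_i||^2 + lambda ||c_i||_1`` over the landmark dictionary
``D``, with ``lambda`` scaled per cell as ``alpha * ||D^T x_i||_inf`` (the
value above which the solution is identically zero), ``alpha = 0.05`` by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.cluster import KMeans
from sklearn.linear_model import Lasso

from mihckit.fixtures import MARKER_PANEL

#: Pan-immune CD45 mean-intensity cut-off (strictly greater-than retains).
CD45_CUTOFF = 0.07


@dataclass
class FeatureMatrix:
    """m x N marker-by-cell matrix with its normalization record."""

    X: np.ndarray
    cell_ids: np.ndarray
    markers: list[str]
    normalization: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]


@dataclass
class SSCModel:
    """Fitted landmark-SSC model: codes, affinity, labels and diagnostics."""

    landmarks: np.ndarray
    C: np.ndarray  # L x N sparse coefficient matrix
    W: np.ndarray  # N x N symmetric non-negative affinity, zero diagonal
    labels: np.ndarray  # group per cell, in 1..k
    k: int
    alpha: float
    cell_ids: np.ndarray
    diagnostics: dict = field(default_factory=dict)


def filter_immune(cells: pd.DataFrame, cd45_cutoff: float = CD45_CUTOFF) -> pd.DataFrame:
    """Retain immune cells: rows with CD45 strictly greater than the cut-off."""
    if "CD45" not in cells.columns:
        raise KeyError("cell table has no CD45 column")
    return cells.loc[cells["CD45"].to_numpy(dtype=float) > cd45_cutoff].copy()


def build_feature_matrix(
    cells: pd.DataFrame,
    markers: list[str] | None = None,
    normalization: str = "none",
) -> FeatureMatrix:
    """Assemble the marker-by-cell matrix used for coding.

    ``normalization``: ``none`` (raw intensities), ``max`` (each marker scaled
    by its maximum, so every row's max is 1), or ``zscore`` (per-marker mean 0
    / SD 1; zero-variance markers are an error).  The applied record is stored
    so profiles can be mapped back to the raw scale.
    """
    markers = list(markers) if markers is not None else list(MARKER_PANEL)
    missing = [m for m in markers if m not in cells.columns]
    if missing:
        raise KeyError(f"cell table lacks markers {missing}")
    X = cells[markers].to_numpy(dtype=float).T.copy()
    if np.isnan(X).any():
        raise ValueError("missing values in marker intensities")
    record: dict = {"mode": normalization}
    if normalization == "none":
        pass
    elif normalization == "max":
        scale = X.max(axis=1, keepdims=True)
        scale[scale == 0] = 1.0
        X = X / scale
        record["scale"] = scale.ravel()
    elif normalization == "zscore":
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        if np.any(sd < 1e-12):
            bad = [markers[i] for i in np.flatnonzero(sd.ravel() < 1e-12)]
            raise ValueError(f"zero-variance markers under z-score mode: {bad}")
        X = (X - mu) / sd
        record["mean"], record["sd"] = mu.ravel(), sd.ravel()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    ids = (
        cells["cell_id"].to_numpy()
        if "cell_id" in cells.columns
        else np.arange(len(cells))
    )
    return FeatureMatrix(X=X, cell_ids=np.asarray(ids), markers=markers,
                         normalization=record)


def select_landmarks(
    fm: FeatureMatrix,
    n_landmarks: int,
    method: str = "kmeans",
    seed: int = 0,
) -> np.ndarray:
    """Choose landmark cell indices (sorted, unique; deterministic per seed).

    ``kmeans`` clusters cells into ``n_landmarks`` groups and takes the cell
    nearest each center; ``random`` samples uniformly without replacement.
    """
    N = fm.n_cells
    if not 1 <= n_landmarks <= N:
        raise ValueError(f"n_landmarks must be in [1, {N}]")
    if n_landmarks == N:
        return np.arange(N)
    rng = np.random.default_rng(seed)
    if method == "random":
        return np.sort(rng.choice(N, size=n_landmarks, replace=False))
    if method != "kmeans":
        raise ValueError(f"unknown landmark method {method!r}")
    km = KMeans(n_clusters=n_landmarks, random_state=seed, n_init=4)
    km.fit(fm.X.T)
    chosen: list[int] = []
    taken = np.zeros(N, dtype=bool)
    for center in km.cluster_centers_:
        d = np.linalg.norm(fm.X.T - center, axis=1)
        d[taken] = np.inf
        idx = int(np.argmin(d))
        chosen.append(idx)
        taken[idx] = True
    return np.sort(np.array(chosen))


def sparse_code(
    fm: FeatureMatrix,
    landmarks: np.ndarray,
    alpha: float = 0.05,
    lam: float | None = None,
    solver_tol: float = 1e-8,
    max_iter: int = 50_000,
) -> np.ndarray:
    """Sparse self-expressive codes of every cell over the landmark dictionary.

    Solves, per cell, ``min_c 1/2 ||x_i - D c||^2 + lambda_i ||c||_1`` with
    ``D`` the landmark columns of ``X``; when cell ``i`` is itself a landmark
    its own dictionary column is excluded, enforcing the zero self-coefficient
    that rules out the trivial self-representation.  ``lambda_i`` defaults to
    ``alpha * ||D^T x_i||_inf`` (``lam`` overrides with a fixed value).
    Returns the L x N coefficient matrix; non-converged cells are flagged in
    the model diagnostics by the caller.
    """
    landmarks = np.asarray(landmarks, dtype=int)
    if landmarks.size == 0:
        raise ValueError("landmarks must be non-empty")
    if alpha < 0 or (lam is not None and lam < 0):
        raise ValueError("sparsity weight must be non-negative")
    X = fm.X
    m, N = X.shape
    L = landmarks.size
    D = X[:, landmarks]
    land_pos = {int(idx): j for j, idx in enumerate(landmarks)}
    C = np.zeros((L, N))

    for i in range(N):
        x = X[:, i]
        self_j = land_pos.get(i)
        if self_j is None:
            Di, cols = D, None
        else:
            cols = np.r_[0:self_j, self_j + 1 : L]
            Di = D[:, cols]
        if Di.shape[1] == 0:
            continue
        corr = np.abs(Di.T @ x).max()
        lam_i = lam if lam is not None else alpha * corr
        if corr < 1e-15 or lam_i < 1e-15:
            coef = np.linalg.lstsq(Di, x, rcond=None)[0]
        else:
            # sklearn Lasso objective is (1/(2 m)) ||x - D c||^2 + a ||c||_1
            model = Lasso(
                alpha=lam_i / m,
                fit_intercept=False,
                tol=solver_tol,
                max_iter=max_iter,
            )
            model.fit(Di, x)
            coef = model.coef_
        if cols is None:
            C[:, i] = coef
        else:
            C[cols, i] = coef
    return C


def _affinity_from_codes(C: np.ndarray, landmarks: np.ndarray, n_cells: int) -> np.ndarray:
    """Symmetric non-negative affinity with zero diagonal from sparse codes.

    When every cell is a landmark this is the classic ``|C| + |C|^T``.
    Otherwise two cells are similar when they load on shared landmarks: the
    columns of ``|C|`` are l2-normalized and ``W = Chat^T Chat``.
    """
    A = np.abs(C)
    L, N = A.shape
    if L == N and np.array_equal(landmarks, np.arange(N)):
        W = A + A.T
    else:
        norms = np.linalg.norm(A, axis=0, keepdims=True)
        norms[norms == 0] = 1.0
        Ahat = A / norms
        W = Ahat.T @ Ahat
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    return np.clip(W, 0.0, None)


def _diffusion_embedding(W: np.ndarray, k: int) -> np.ndarray:
    """Top-k eigenvectors of the normalized affinity, weighted by eigenvalue².

    The squared-eigenvalue (diffusion time 2) weighting damps noise
    directions, which keeps the dispersion curve used for model selection
    sensitive to genuine cluster structure while a structureless cloud stays
    elbow-free.
    """
    d = W.sum(axis=1)
    d = np.where(d > 1e-12, d, 1e-12)
    dinv = 1.0 / np.sqrt(d)
    M = W * dinv[:, None] * dinv[None, :]
    n = M.shape[0]
    vals, vecs = eigh(M, subset_by_index=(n - k, n - 1))
    return vecs[:, ::-1] * np.clip(vals[::-1], 0.0, None) ** 2


def _spectral_embedding(W: np.ndarray, k: int) -> np.ndarray:
    """Top-k eigenvectors of the normalized affinity, row-normalized."""
    d = W.sum(axis=1)
    d = np.where(d > 1e-12, d, 1e-12)
    dinv = 1.0 / np.sqrt(d)
    M = W * dinv[:, None] * dinv[None, :]
    n = M.shape[0]
    vals, vecs = eigh(M, subset_by_index=(n - k, n - 1))
    emb = vecs[:, ::-1]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return emb / norms


def cluster_from_codes(
    C: np.ndarray,
    k: int,
    seed: int = 0,
    landmarks: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Spectral clustering of the code-derived affinity into ``k`` groups.

    Returns ``(labels, W)`` with labels in 1..k.  The affinity is always
    symmetric, non-negative, zero-diagonal; the embedding uses the normalized
    graph Laplacian and k-means with a fixed seed.
    """
    L, N = C.shape
    if not 1 <= k <= N:
        raise ValueError(f"k must be in [1, {N}]")
    landmarks = np.arange(N) if landmarks is None else np.asarray(landmarks)
    W = _affinity_from_codes(C, landmarks, N)
    if k == 1:
        return np.ones(N, dtype=int), W
    emb = _spectral_embedding(W, k)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(emb) + 1
    return labels, W


def choose_k(
    fm_or_W: FeatureMatrix | np.ndarray,
    k_range,
    seed: int = 0,
    alpha: float = 0.05,
    n_landmarks: int | None = None,
    elbow_threshold: float = 0.5,
) -> tuple[int, pd.DataFrame]:
    """Pick the number of groups by the elbow of the spectral-embedding WCSS.

    For each candidate ``k`` the within-cluster sum of squares of k-means in
    the k-dimensional spectral embedding is computed; the elbow is the point
    of maximum distance below the chord joining the normalized curve's
    endpoints (kneedle-style).  If no point falls more than
    ``elbow_threshold`` below the chord the curve is deemed elbow-free and
    the smallest candidate is returned.  The full curve is returned for
    inspection.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("k_range must be non-empty")
    if isinstance(fm_or_W, FeatureMatrix):
        N = fm_or_W.n_cells
        nl = min(n_landmarks or min(2000, N), N)
        lm = select_landmarks(fm_or_W, nl, seed=seed)
        C = sparse_code(fm_or_W, lm, alpha=alpha)
        W = _affinity_from_codes(np.asarray(C), lm, N)
    else:
        W = np.asarray(fm_or_W, dtype=float)
        N = W.shape[0]
    if k_range[-1] > N:
        raise ValueError("k_range exceeds the number of cells")
    if len(k_range) == 1:
        return k_range[0], pd.DataFrame({"k": k_range, "wcss": [np.nan]})

    # one eigenvalue-weighted embedding of dimension max(k_range) hosts the
    # whole WCSS curve, so candidate k values are compared in a common space
    emb = _diffusion_embedding(W, k_range[-1])
    wcss = []
    for k in k_range:
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        km.fit(emb)
        wcss.append(km.inertia_)
    curve = pd.DataFrame({"k": k_range, "wcss": wcss})

    y = np.asarray(wcss, dtype=float)
    span = y.max() - y.min()
    if span < 1e-12:
        return k_range[0], curve
    yn = (y - y.min()) / span
    xn = (np.asarray(k_range, float) - k_range[0]) / (k_range[-1] - k_range[0])
    below_chord = (1.0 - xn) - yn  # chord of the normalized decreasing curve
    best = int(np.argmax(below_chord))
    if below_chord[best] < elbow_threshold:
        return k_range[0], curve
    return k_range[best], curve


def cluster_profiles(
    labels: np.ndarray,
    cells: pd.DataFrame,
    markers: list[str] | None = None,
) -> pd.DataFrame:
    """Mean marker intensity per group, with group sizes, ordered by group id."""
    markers = list(markers) if markers is not None else [
        m for m in MARKER_PANEL if m in cells.columns
    ]
    labels = np.asarray(labels)
    if len(labels) != len(cells):
        raise ValueError("labels and cell table length mismatch")
    df = cells[markers].copy()
    df["group"] = labels
    prof = df.groupby("group").mean().sort_index()
    prof["n_cells"] = df.groupby("group").size()
    return prof


def fit_ssc(
    cells: pd.DataFrame,
    k: int = 20,
    markers: list[str] | None = None,
    normalization: str = "none",
    n_landmarks: int | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    cd45_cutoff: float | None = None,
) -> SSCModel:
    """End-to-end landmark SSC on a single-cell table.

    Optionally pre-filters to immune cells (``cd45_cutoff``), builds the
    feature matrix, selects landmarks (default ``min(2000, N)`` k-means
    representatives), sparse-codes every cell, and spectrally clusters the
    affinity into ``k`` groups (default 20).
    """
    if cd45_cutoff is not None:
        cells = filter_immune(cells, cd45_cutoff)
    if len(cells) == 0:
        raise ValueError("no cells to cluster after filtering")
    fm = build_feature_matrix(cells, markers, normalization)
    nl = min(n_landmarks or min(2000, fm.n_cells), fm.n_cells)
    lm = select_landmarks(fm, nl, seed=seed)
    C = sparse_code(fm, lm, alpha=alpha)
    labels, W = cluster_from_codes(C, k=k, seed=seed, landmarks=lm)
    return SSCModel(
        landmarks=lm,
        C=C,
        W=W,
        labels=labels,
        k=k,
        alpha=alpha,
        cell_ids=fm.cell_ids,
        diagnostics={
            "n_cells": fm.n_cells,
            "n_landmarks": int(lm.size),
            "normalization": fm.normalization,
            "affinity": "|C|+|C|T" if lm.size == fm.n_cells
            else "shared-landmark (ChatT Chat)",
        },
    )
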