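"""Sparse-subspace clustering: convex-program oracle, subspace preservation,
recovery of planted structure, and concordance with gating."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from sklearn.metrics import adjusted_rand_score

from mihckit.fixtures import default_archetypes, synth_cell_table
from mihckit.gating import apply_gating_tree, default_gating_tree
from mihckit.ssc import (
    build_feature_matrix,
    choose_k,
    cluster_from_codes,
    cluster_profiles,
    filter_immune,
    fit_ssc,
    select_landmarks,
    sparse_code,
)


def lasso_oracle(D: np.ndarray, x: np.ndarray, lam: float) -> np.ndarray:
    """Independent convex-program solver for 1/2||x - Dc||^2 + lam ||c||_1.

    Split c into non-negative parts c = u - v and minimize the smooth QP over
    the non-negative orthant with L-BFGS-B — no coordinate descent, no
    sklearn.
    """
    L = D.shape[1]

    def f(z):
        u, v = z[:L], z[L:]
        c = u - v
        r = x - D @ c
        return 0.5 * r @ r + lam * (u.sum() + v.sum())

    def grad(z):
        u, v = z[:L], z[L:]
        r = D @ (u - v) - x
        g = D.T @ r
        return np.concatenate([g + lam, -g + lam])

    res = minimize(
        f, np.zeros(2 * L), jac=grad, method="L-BFGS-B",
        bounds=[(0, None)] * (2 * L),
        options={"maxiter": 20000, "ftol": 1e-14, "gtol": 1e-10},
    )
    u, v = res.x[:L], res.x[L:]
    return u - v


def _fm(X: np.ndarray) -> "object":
    cells = pd.DataFrame(X, columns=[f"M{i}" for i in range(X.shape[1])])
    cells["cell_id"] = np.arange(len(cells))
    return build_feature_matrix(cells, markers=[f"M{i}" for i in range(X.shape[1])])


def _three_subspace_fixture(n_per=200, noise=0.05, seed=11):
    rng = np.random.default_rng(seed)
    dirs = np.linalg.qr(rng.normal(size=(10, 3)))[0].T
    X, truth = [], []
    for j in range(3):
        scales = rng.uniform(0.5, 1.5, size=n_per)
        X.append(np.outer(scales, dirs[j]) + rng.normal(0, noise, (n_per, 10)))
        truth += [j] * n_per
    return np.vstack(X), np.array(truth)


class TestFilterAndFeatures:
    def test_cd45_strictly_greater(self):
        cells = pd.DataFrame({"CD45": [0.08, 0.07, 0.06], "cell_id": [1, 2, 3]})
        kept = filter_immune(cells)
        assert list(kept.cell_id) == [1]

    def test_zero_cutoff_keeps_all_positive(self):
        cells = pd.DataFrame({"CD45": [0.01, 0.5], "cell_id": [1, 2]})
        assert len(filter_immune(cells, cd45_cutoff=0.0)) == 2

    def test_planted_high_count_matches_column_scan(self, archetypes):
        table = synth_cell_table(
            archetypes, {"B cells": 200, "Epithelial cells": 300}, noise_seed=21
        )
        kept = filter_immune(table)
        brute = sum(1 for v in table["CD45"] if v > 0.07)
        assert len(kept) == brute

    def test_missing_cd45_rejected(self):
        with pytest.raises(KeyError):
            filter_immune(pd.DataFrame({"CD3": [1.0]}))

    def test_normalization_modes(self, archetypes):
        table = synth_cell_table(archetypes, {"B cells": 50}, noise_seed=2)
        raw = build_feature_matrix(table, normalization="none")
        assert np.allclose(raw.X.T, table[list(raw.markers)].to_numpy())
        mx = build_feature_matrix(table, normalization="max")
        assert np.allclose(mx.X.max(axis=1), 1.0)
        z = build_feature_matrix(table, normalization="zscore")
        assert np.allclose(z.X.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.X.std(axis=1), 1, atol=1e-9)

    def test_zero_variance_zscore_rejected(self):
        cells = pd.DataFrame({f"M{i}": np.ones(10) for i in range(3)})
        with pytest.raises(ValueError, match="zero-variance"):
            build_feature_matrix(cells, markers=["M0", "M1", "M2"],
                                 normalization="zscore")


class TestLandmarks:
    def test_all_cells_when_n_equals_N(self):
        X, _ = _three_subspace_fixture(n_per=20)
        fm = _fm(X)
        assert np.array_equal(select_landmarks(fm, fm.n_cells), np.arange(fm.n_cells))

    def test_kmeans_landmarks_cover_blobs(self):
        rng = np.random.default_rng(4)
        centers = np.array([[0, 0], [10, 0], [0, 10]], float)
        X = np.vstack([c + rng.normal(0, 0.3, (100, 2)) for c in centers])
        cells = pd.DataFrame(X, columns=["M0", "M1"])
        fm = build_feature_matrix(cells, markers=["M0", "M1"])
        lm = select_landmarks(fm, 30, seed=0)
        blob = lm // 100
        assert set(blob) == {0, 1, 2}

    def test_deterministic_and_bounds(self):
        X, _ = _three_subspace_fixture(n_per=20)
        fm = _fm(X)
        a = select_landmarks(fm, 10, method="random", seed=5)
        b = select_landmarks(fm, 10, method="random", seed=5)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            select_landmarks(fm, fm.n_cells + 1)


class TestSparseCode:
    def test_exact_landmark_copy_recovers_indicator(self):
        # a cell equal to one unit-norm landmark, tiny lambda -> c ~ e_j
        rng = np.random.default_rng(7)
        D = np.linalg.qr(rng.normal(size=(8, 4)))[0]  # orthonormal landmarks
        X = np.hstack([D, D[:, [2]]]).T  # last cell copies landmark 2
        fm = _fm(X)
        C = sparse_code(fm, landmarks=np.arange(4), alpha=1e-4)
        c = C[:, 4]
        assert c[2] == pytest.approx(1.0, abs=1e-3)
        assert np.abs(np.delete(c, 2)).max() < 1e-3

    def test_landmark_self_coefficient_is_zero(self):
        X, _ = _three_subspace_fixture(n_per=10)
        fm = _fm(X)
        lm = np.arange(fm.n_cells)
        C = sparse_code(fm, lm, alpha=0.05)
        assert np.allclose(np.diag(C), 0.0)

    def test_agrees_with_convex_oracle(self):
        rng = np.random.default_rng(9)
        D = rng.normal(size=(6, 3))
        x = rng.normal(size=6)
        lam = 0.05 * np.abs(D.T @ x).max()
        X = np.hstack([D, x[:, None]]).T
        fm = _fm(X)
        C = sparse_code(fm, landmarks=np.arange(3), lam=lam)
        expected = lasso_oracle(D, x, lam)
        assert np.allclose(C[:, 3], expected, atol=1e-5)

    def test_subspace_preserving_support_on_orthogonal_subspaces(self):
        # two orthogonal 1-D subspaces, 10 noiseless points each: every code's
        # support stays within its own subspace, and matches the oracle
        rng = np.random.default_rng(13)
        e1 = np.zeros(6); e1[0] = 1.0
        e2 = np.zeros(6); e2[3] = 1.0
        pts = [s * e1 for s in rng.uniform(0.5, 2.0, 10)] + [
            s * e2 for s in rng.uniform(0.5, 2.0, 10)
        ]
        X = np.array(pts)
        fm = _fm(X)
        lm = np.arange(20)
        C = sparse_code(fm, lm, alpha=0.05)
        for i in range(20):
            own = range(10) if i < 10 else range(10, 20)
            support = np.flatnonzero(np.abs(C[:, i]) > 1e-8)
            assert len(support) > 0
            assert set(support) <= set(own)
            # cross-check one column against the independent solver
            if i in (0, 15):
                D = np.delete(X.T, i, axis=1)
                lam = 0.05 * np.abs(D.T @ X[i]).max()
                oracle = lasso_oracle(D, X[i], lam)
                full = np.insert(oracle, i, 0.0)
                assert np.allclose(C[:, i], full, atol=1e-5)


class TestClustering:
    def test_block_diagonal_affinity_two_blocks(self):
        W = np.zeros((6, 6))
        W[:3, :3] = 1.0
        W[3:, 3:] = 1.0
        np.fill_diagonal(W, 0)
        # feed W through the spectral step by treating it as codes of an
        # all-landmark model: |C|+|C|^T = 2W has the same blocks
        labels, Wout = cluster_from_codes(W, k=2, seed=0)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]
        assert np.allclose(Wout, Wout.T) and np.allclose(np.diag(Wout), 0)

    def test_planted_three_subspaces_ari(self):
        X, truth = _three_subspace_fixture(n_per=200, noise=0.05, seed=11)
        fm = _fm(X)
        lm = select_landmarks(fm, 100, seed=11)
        C = sparse_code(fm, lm)
        labels, _ = cluster_from_codes(C, 3, seed=11, landmarks=lm)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_permutation_invariance_up_to_relabel(self):
        X, truth = _three_subspace_fixture(n_per=50, seed=3)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(X))
        fm1, fm2 = _fm(X), _fm(X[perm])
        l1, _ = cluster_from_codes(
            sparse_code(fm1, np.arange(len(X))), 3, seed=5
        )
        l2, _ = cluster_from_codes(
            sparse_code(fm2, np.arange(len(X))), 3, seed=5
        )
        assert adjusted_rand_score(l1[perm], l2) == 1.0


class TestChooseK:
    def test_three_blobs_elbow_at_three(self):
        X, _ = _three_subspace_fixture(n_per=80, noise=0.03, seed=2)
        fm = _fm(X)
        k, curve = choose_k(fm, range(1, 9), seed=2, n_landmarks=60)
        assert k == 3

    def test_single_cloud_returns_smallest_k(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(150, 10))
        fm = _fm(X)
        k, _ = choose_k(fm, range(1, 7), seed=6, n_landmarks=60)
        assert k == 1

    def test_singleton_range(self):
        X, _ = _three_subspace_fixture(n_per=20)
        fm = _fm(X)
        k, _ = choose_k(fm, [4], seed=0)
        assert k == 4


class TestProfilesAndPipeline:
    def test_single_group_profile_is_global_mean(self, archetypes):
        table = synth_cell_table(archetypes, {"B cells": 30}, noise_seed=1)
        prof = cluster_profiles(np.ones(30, dtype=int), table)
        for m in prof.columns.drop("n_cells"):
            assert prof.loc[1, m] == pytest.approx(table[m].mean())

    def test_archetype_groups_show_their_marker_structure(self, archetypes):
        wanted = ["B cells", "CD8+ T cells", "CD163+ myelomonocytic cells"]
        table = synth_cell_table(
            archetypes, {w: 120 for w in wanted}, noise_seed=8
        )
        model = fit_ssc(table, k=3, n_landmarks=90, seed=0)
        prof = cluster_profiles(model.labels, table)
        by_label = {a.label: a for a in archetypes}
        # map each group to its dominant truth label, then check +/- ordering
        for g in prof.index:
            members = table.loc[model.labels == g, "true_label"]
            arch = by_label[members.mode().iloc[0]]
            pos = arch.positive_markers()
            neg = [m for m in arch.marker_signs if m not in pos]
            assert prof.loc[g, pos].min() > prof.loc[g, neg].max()

    def test_ssc_concordant_with_gating_on_archetypes(self, archetypes):
        counts = {a.label: 150 for a in archetypes if a.label != "Epithelial cells"}
        table = synth_cell_table(archetypes, counts, noise_seed=5)
        immune = filter_immune(table)
        model = fit_ssc(immune, k=len(counts), n_landmarks=200, seed=0)
        gates = apply_gating_tree(immune, default_gating_tree())
        assert adjusted_rand_score(gates.to_numpy(), model.labels) >= 0.8

    def test_affinity_invariants_on_fit(self, archetypes):
        table = synth_cell_table(
            archetypes, {"B cells": 60, "CD8+ T cells": 60}, noise_seed=4
        )
        model = fit_ssc(table, k=2, n_landmarks=40, seed=1)
        W = model.W
        assert np.allclose(W, W.T)
        assert W.min() >= 0
        assert np.allclose(np.diag(W), 0)
        # end-to-end determinism
        model2 = fit_ssc(table, k=2, n_landmarks=40, seed=1)
        assert np.array_equal(model.labels, model2.labels)
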