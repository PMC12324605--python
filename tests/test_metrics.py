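"""Every metric against an independent brute-force implementation, plus
the analytic identities and invariances each one must satisfy."""

import numpy as np
import pytest
from scipy.stats import pearsonr, spearmanr

import protomap as pm
from protomap.metrics import knn_weight_matrix


class TestPerCellMetrics:
    def test_perfect_prediction_gives_ones(self):
        x = np.random.default_rng(0).uniform(size=(5, 8))
        rep = pm.per_cell_metrics(x, x)
        assert np.allclose(rep.cosine, 1.0)
        assert np.allclose(rep.pearson, 1.0)
        assert np.allclose(rep.spearman, 1.0)

    def test_affine_transform_preserves_correlations_not_cosine(self):
        x = np.random.default_rng(1).uniform(size=(6, 10))
        rep = pm.per_cell_metrics(x, 2.0 * x + 3.0)
        assert np.allclose(rep.pearson, 1.0)
        assert np.allclose(rep.spearman, 1.0)
        assert rep.mean_cosine < 1.0

    def test_matches_scipy_loop_oracle(self):
        rng = np.random.default_rng(2)
        truth = rng.uniform(size=(10, 20))
        pred = rng.uniform(size=(10, 20))
        rep = pm.per_cell_metrics(truth, pred)
        for i in range(10):
            cos = truth[i] @ pred[i] / (np.linalg.norm(truth[i])
                                        * np.linalg.norm(pred[i]))
            assert abs(rep.cosine[i] - cos) < 1e-9
            assert abs(rep.pearson[i] - pearsonr(truth[i], pred[i])[0]) < 1e-9
            assert abs(rep.spearman[i] - spearmanr(truth[i], pred[i])[0]) < 1e-9

    def test_zero_variance_cells_excluded_and_counted(self):
        truth = np.vstack([np.full(5, 3.0), np.arange(5.0)])
        pred = np.vstack([np.arange(5.0), np.arange(5.0)])
        rep = pm.per_cell_metrics(truth, pred)
        assert rep.n_excluded == 1
        assert rep.mean_pearson == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pm.per_cell_metrics(np.zeros((2, 3)), np.zeros((3, 2)))


class TestFoscttm:
    def test_identical_sets_give_zero(self):
        Z = np.random.default_rng(3).standard_normal((30, 8))
        assert pm.foscttm(Z, Z) == 0.0

    def test_true_match_always_farthest_gives_one(self):
        # each point's partner is the unique farthest opposite point
        Z_a = np.array([[0.0], [1.0]])
        Z_b = np.array([[1.0], [0.0]])
        assert pm.foscttm(Z_a, Z_b) == 1.0

    def test_matches_loop_oracle_with_average_ranks(self):
        rng = np.random.default_rng(4)
        Z_a = rng.standard_normal((20, 5))
        Z_b = rng.standard_normal((20, 5))
        vals = []
        for i in range(20):
            d = np.linalg.norm(Z_a[i] - Z_b, axis=1)
            less = (d < d[i]).sum()
            eq = (d == d[i]).sum()
            vals.append((less + (eq + 1) / 2 - 1) / 19)
        assert abs(pm.foscttm(Z_a, Z_b) - np.mean(vals)) < 1e-12

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(5)
        Z_a = rng.standard_normal((25, 3))
        Z_b = rng.standard_normal((25, 3))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        shift = np.array([2.0, -1.0, 0.5])
        before = pm.foscttm(Z_a, Z_b), pm.match_score(Z_a, Z_b)
        after = (pm.foscttm(Z_a @ R + shift, Z_b @ R + shift),
                 pm.match_score(Z_a @ R + shift, Z_b @ R + shift))
        assert before[0] == pytest.approx(after[0], abs=1e-9)
        assert before[1] == after[1]

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pm.foscttm(np.zeros((1, 2)), np.zeros((1, 2)))


class TestMatchScore:
    def test_identical_sets_give_one(self):
        Z = np.random.default_rng(6).standard_normal((15, 4))
        assert pm.match_score(Z, Z) == 1.0

    def test_cyclic_shift_gives_zero(self):
        Z = np.random.default_rng(7).standard_normal((15, 4))
        assert pm.match_score(Z, np.roll(Z, 1, axis=0)) == 0.0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(8)
        Z_a = rng.standard_normal((30, 6))
        Z_b = rng.standard_normal((30, 6))
        hits = sum(
            int(np.argmin(np.linalg.norm(Z_a[i] - Z_b, axis=1)) == i)
            for i in range(30))
        assert pm.match_score(Z_a, Z_b) == pytest.approx(hits / 30, abs=1e-12)


class TestCelltypeRetrieval:
    def test_full_k_hits_every_present_label(self):
        rng = np.random.default_rng(9)
        Zq = rng.standard_normal((12, 4))
        Zr = rng.standard_normal((20, 4))
        labels_q = ["a"] * 6 + ["b"] * 6
        labels_r = ["a"] * 10 + ["b"] * 10
        curve, _ = pm.celltype_retrieval(Zq, Zr, labels_q, labels_r,
                                         k_percents=[100])
        assert curve[0][1] == 1.0

    def test_collapsed_reference_gives_perfect_top1(self):
        anchors = {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])}
        Zr = np.stack([anchors["a"], anchors["b"]])
        Zq = np.stack([anchors["a"], anchors["a"], anchors["b"]])
        _, acc = pm.celltype_retrieval(Zq, Zr, ["a", "a", "b"], ["a", "b"])
        assert acc == 1.0

    def test_curve_is_monotone_in_k(self):
        rng = np.random.default_rng(10)
        curve, _ = pm.celltype_retrieval(
            rng.standard_normal((30, 5)), rng.standard_normal((40, 5)),
            rng.choice(["a", "b", "c"], 30), rng.choice(["a", "b", "c"], 40),
            k_percents=[1, 5, 20, 50, 100])
        accs = [v for _, v in curve]
        assert accs == sorted(accs)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pm.celltype_retrieval(np.zeros((2, 2)), np.zeros((0, 2)),
                                  ["a", "b"], [])


class TestMoransI:
    def test_smooth_gradient_is_strongly_positive(self):
        g = np.linspace(0, 1, 20)
        xx, yy = np.meshgrid(g, g)
        coords = np.column_stack([xx.ravel(), yy.ravel()])
        assert pm.morans_i(coords[:, 0], coords, k=8) > 0.9

    def test_checkerboard_with_rook_neighbors_is_negative(self):
        g = np.arange(10.0)
        xx, yy = np.meshgrid(g, g)
        coords = np.column_stack([xx.ravel(), yy.ravel()])
        values = ((xx + yy) % 2).ravel()
        assert pm.morans_i(values, coords, k=4) < 0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(size=(25, 2))
        values = rng.uniform(size=25)
        W = knn_weight_matrix(coords, k=5)
        z = values - values.mean()
        num = sum(W[i, j] * z[i] * z[j] for i in range(25) for j in range(25))
        expected = 25 / W.sum() * num / (z**2).sum()
        assert pm.morans_i(values, coords, k=5) == pytest.approx(expected,
                                                                 abs=1e-9)

    def test_constant_field_rejected(self):
        coords = np.random.default_rng(12).uniform(size=(20, 2))
        with pytest.raises(ValueError, match="constant"):
            pm.morans_i(np.ones(20), coords, k=4)


class TestMMD:
    def test_identical_weighted_sets_give_zero(self):
        pts = np.random.default_rng(13).uniform(size=(12, 2))
        w = np.random.default_rng(14).uniform(size=12)
        assert pm.cell_level_mmd(pts, pts, 0.1, w, w) == pytest.approx(0.0,
                                                                       abs=1e-12)

    def test_two_point_closed_form(self):
        for D in (0.1, 0.5, 2.0):
            for blur in (0.05, 0.2, 1.0):
                val = pm.cell_level_mmd(np.array([[0.0, 0.0]]),
                                        np.array([[D, 0.0]]), blur)
                expected = 2 * (1 - np.exp(-D**2 / (2 * blur**2)))
                assert val == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_translation_distance(self):
        rng = np.random.default_rng(15)
        cloud = rng.uniform(size=(30, 2))
        vals = [pm.cell_level_mmd(cloud, cloud + [dx, 0.0], 0.2)
                for dx in (0.0, 0.1, 0.2, 0.4, 0.8)]
        assert all(b > a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(16)
        A, B = rng.uniform(size=(10, 2)), rng.uniform(size=(15, 2))
        wa, wb = rng.uniform(size=10), rng.uniform(size=15)
        assert pm.cell_level_mmd(A, B, 0.3, wa, wb) == pytest.approx(
            pm.cell_level_mmd(B, A, 0.3, wb, wa), abs=1e-12)

    def test_matches_weighted_loop_oracle(self):
        rng = np.random.default_rng(17)
        A, B = rng.uniform(size=(8, 2)), rng.uniform(size=(9, 2))
        wa = rng.uniform(size=8)
        wb = rng.uniform(size=9)
        blur = 0.25
        na, nb = wa / wa.sum(), wb / wb.sum()

        def k(p, q):
            return np.exp(-((p - q)**2).sum() / (2 * blur**2))

        expected = (
            sum(na[i] * na[j] * k(A[i], A[j]) for i in range(8) for j in range(8))
            + sum(nb[i] * nb[j] * k(B[i], B[j]) for i in range(9) for j in range(9))
            - 2 * sum(na[i] * nb[j] * k(A[i], B[j]) for i in range(8)
                      for j in range(9)))
        assert pm.cell_level_mmd(A, B, blur, wa, wb) == pytest.approx(
            expected, abs=1e-6)

    def test_blur_list_returns_one_value_per_scale(self):
        pts = np.random.default_rng(18).uniform(size=(5, 2))
        out = pm.cell_level_mmd(pts, pts + 0.3, [0.05, 0.1, 0.5])
        assert len(out) == 3

    def test_invalid_weights_rejected(self):
        pts = np.zeros((3, 2))
        with pytest.raises(ValueError, match="positive"):
            pm.cell_level_mmd(pts, pts, 0.1, np.zeros(3), np.ones(3))
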