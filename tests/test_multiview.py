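import numpy as np
import pandas as pd
import pytest

from pathblend import block_importance, fit_mbpls, mb_vip, predict, vip
from pathblend.multiview import MBPLSModel


def hand_pls1(X, y, R):
    """Reference single-block NIPALS PLS1, written independently:
    w = X'y / ||X'y||, t = Xw, deflate by t; beta = W (P'W)^-1 C."""
    Xd = X.copy()
    yd = y.astype(float).copy()
    W, P, C, T = [], [], [], []
    for _ in range(R):
        w = Xd.T @ yd
        w = w / np.linalg.norm(w)
        t = Xd @ w
        c = yd @ t / (t @ t)
        p = Xd.T @ t / (t @ t)
        Xd = Xd - np.outer(t, p)
        yd = yd - c * t
        W.append(w)
        P.append(p)
        C.append(c)
        T.append(t)
    W, P, C = np.array(W).T, np.array(P).T, np.array(C)
    beta = W @ np.linalg.inv(P.T @ W) @ C
    return beta, np.array(T).T, W


def _center_scale(X):
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


@pytest.fixture
def two_blocks(rng):
    X1 = pd.DataFrame(rng.standard_normal((60, 8)))
    X2 = pd.DataFrame(rng.standard_normal((60, 5)))
    X2.columns = [f"b{j}" for j in range(5)]
    y = rng.integers(0, 2, 60)
    return X1, X2, y


class TestFit:
    def test_k1_equals_hand_coded_pls(self, rng):
        X = rng.standard_normal((40, 10))
        y = rng.standard_normal(40)
        m = fit_mbpls([pd.DataFrame(X)], y, R=3)
        Xs = _center_scale(X)
        beta, T, W = hand_pls1(Xs, y - y.mean(), 3)
        pred_ref = Xs @ beta + y.mean()
        np.testing.assert_allclose(predict(m, [X]), pred_ref, atol=1e-8)
        np.testing.assert_allclose(np.abs(m.superscores), np.abs(T), atol=1e-8)

    def test_exact_fit_when_y_spanned_by_column(self, rng):
        # mean-zero orthogonal columns: one LV isolates the spanning column
        M = rng.standard_normal((30, 6))
        Q, _ = np.linalg.qr(M - M.mean(axis=0))
        X = Q
        y = 2.5 * X[:, 3]
        m = fit_mbpls([pd.DataFrame(X)], y, R=1)
        rss = float(np.sum((predict(m, [X]) - y) ** 2))
        assert rss < 1e-12

    def test_hand_worked_toy_two_blocks(self):
        """4 samples, 2 blocks of 2 integer features, R=1; compare every
        quantity with a step-by-step NIPALS computation done in plain
        numpy below (no shared code with the implementation)."""
        X1 = np.array([[1.0, 2.0], [3.0, 1.0], [2.0, 4.0], [4.0, 3.0]])
        X2 = np.array([[2.0, 0.0], [1.0, 1.0], [3.0, 2.0], [0.0, 3.0]])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        m = fit_mbpls(
            [pd.DataFrame(X1), pd.DataFrame(X2)], y, R=1, scale=False
        )

        # independent step-by-step computation
        Z1 = X1 - X1.mean(axis=0)
        Z2 = X2 - X2.mean(axis=0)
        u = y - y.mean()
        t_s_old = None
        for _ in range(200):
            w1 = Z1.T @ u / np.linalg.norm(Z1.T @ u)
            w2 = Z2.T @ u / np.linalg.norm(Z2.T @ u)
            T = np.column_stack([Z1 @ w1, Z2 @ w2])
            a = T.T @ u / np.linalg.norm(T.T @ u)
            t_s = T @ a
            c = u @ t_s / (t_s @ t_s)
            if t_s_old is not None and np.linalg.norm(t_s - t_s_old) < 1e-14:
                break
            t_s_old = t_s
        if a[np.argmax(np.abs(a))] < 0:
            a, t_s, c = -a, -t_s, -c
        np.testing.assert_allclose(m.superscores[:, 0], t_s, atol=1e-10)
        np.testing.assert_allclose(m.superweights[0], a, atol=1e-10)
        np.testing.assert_allclose(m.block_weights[0][0], w1, atol=1e-10)
        np.testing.assert_allclose(m.block_weights[0][1], w2, atol=1e-10)
        np.testing.assert_allclose(m.y_weights[0], c, atol=1e-10)

    def test_rank_exceeded_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        with pytest.raises(ValueError, match="rank"):
            fit_mbpls([pd.DataFrame(X)], y, R=5)


class TestPredict:
    def test_training_prediction_equals_scores_route(self, two_blocks):
        X1, X2, y = two_blocks
        m = fit_mbpls([X1, X2], y, R=2)
        via_scores = m.superscores @ m.y_weights + m.y_mean
        np.testing.assert_allclose(predict(m, [X1, X2]), via_scores, atol=1e-8)

    def test_all_zero_rows_predict_training_mean(self, two_blocks):
        X1, X2, y = two_blocks
        m = fit_mbpls([X1, X2], y, R=2)
        z1 = pd.DataFrame(
            np.tile(X1.mean().to_numpy(), (3, 1)), columns=X1.columns
        )
        z2 = pd.DataFrame(
            np.tile(X2.mean().to_numpy(), (3, 1)), columns=X2.columns
        )
        np.testing.assert_allclose(predict(m, [z1, z2]), m.y_mean, atol=1e-10)

    def test_beta_route_equals_scores_route_held_out(self, rng, two_blocks):
        X1, X2, y = two_blocks
        m = fit_mbpls([X1, X2], y, R=3)
        H1 = pd.DataFrame(rng.standard_normal((12, 8)), columns=X1.columns)
        H2 = pd.DataFrame(rng.standard_normal((12, 5)), columns=X2.columns)
        # scores route: project deflated blocks LV by LV
        parts = [
            (H.to_numpy() - m.x_means[k]) / m.x_sds[k]
            for k, H in enumerate([H1, H2])
        ]
        Xc = np.hstack(parts)
        pred_scores = np.zeros(12) + m.y_mean
        Xd = Xc.copy()
        for r in range(m.R):
            t = Xd @ m.W_cat[:, r]
            pred_scores += t * m.y_weights[r]
            Xd = Xd - np.outer(t, m.P_cat[:, r])
        np.testing.assert_allclose(predict(m, [H1, H2]), pred_scores, atol=1e-8)

    def test_block_permutation_leaves_prediction_invariant(self, two_blocks):
        X1, X2, y = two_blocks
        m12 = fit_mbpls([X1, X2], y, R=2)
        m21 = fit_mbpls([X2, X1], y, R=2)
        np.testing.assert_allclose(
            predict(m12, [X1, X2]), predict(m21, [X2, X1]), atol=1e-8
        )


class TestImportance:
    def test_k1_block_importance_is_one(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 6)))
        m = fit_mbpls([X], rng.standard_normal(30), R=2)
        bi = block_importance(m)
        np.testing.assert_allclose(bi.drop(columns="aggregate").to_numpy(), 1.0)

    def test_identical_blocks_split_evenly(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 6)))
        X2 = X.copy()
        X2.columns = [f"c{j}" for j in range(6)]
        m = fit_mbpls([X, X2], rng.standard_normal(30), R=2)
        bi = block_importance(m).drop(columns="aggregate")
        np.testing.assert_allclose(bi.to_numpy(), 0.5, atol=1e-8)

    def test_per_lv_fractions_sum_to_one(self, two_blocks):
        X1, X2, y = two_blocks
        m = fit_mbpls([X1, X2], y, R=3)
        bi = block_importance(m).drop(columns="aggregate")
        np.testing.assert_allclose(bi.sum(axis=0).to_numpy(), 1.0, atol=1e-10)


class TestVip:
    def test_single_lv_closed_form(self, rng):
        X = rng.standard_normal((25, 7))
        y = rng.standard_normal(25)
        m = fit_mbpls([pd.DataFrame(X)], y, R=1)
        expected = np.sqrt(7) * np.abs(m.block_weights[0][0])
        np.testing.assert_allclose(vip(m).values.to_numpy(), expected, atol=1e-10)

    def test_mean_squared_vip_is_one(self, rng):
        for seed in (0, 1, 2):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.standard_normal((40, 9)))
            m = fit_mbpls([X], r.integers(0, 2, 40), R=3)
            assert (vip(m).values ** 2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_vip_on_multiblock_directs_to_mb_vip(self, two_blocks):
        X1, X2, y = two_blocks
        m = fit_mbpls([X1, X2], y, R=1)
        with pytest.raises(ValueError, match="mb_vip"):
            vip(m)

    def test_mb_vip_equals_vip_for_k1(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 6)))
        m = fit_mbpls([X], rng.standard_normal(30), R=2)
        np.testing.assert_array_equal(
            vip(m).values.to_numpy(), mb_vip(m).values.to_numpy()
        )

    def test_mb_vip_single_lv_closed_form(self, rng):
        X1 = pd.DataFrame(rng.standard_normal((20, 2)))
        X2 = pd.DataFrame(rng.standard_normal((20, 3)))
        y = rng.standard_normal(20)
        m = fit_mbpls([X1, X2], y, R=1)
        w_cat = np.concatenate([m.block_weights[0][0], m.block_weights[0][1]])
        np.testing.assert_allclose(
            mb_vip(m).values.to_numpy(), np.sqrt(5) * np.abs(w_cat), atol=1e-10
        )

    def test_mb_vip_normalization(self, two_blocks):
        X1, X2, y = two_blocks
        m = fit_mbpls([X1, X2], y, R=3)
        v = mb_vip(m)
        assert (v.values**2).sum() / (v.f * v.k) == pytest.approx(1.0, abs=1e-8)


class TestDeflation:
    def test_superscores_orthogonal(self, two_blocks):
        X1, X2, y = two_blocks
        m = fit_mbpls([X1, X2], y, R=4)
        G = m.superscores.T @ m.superscores
        norms = np.sqrt(np.diag(G))
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off) / np.outer(norms, norms)) < 1e-6

    def test_full_rank_deflation_reaches_ols_residual(self, rng):
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        m = fit_mbpls([pd.DataFrame(X)], y, R=5)
        resid_model = float(np.sum((y - predict(m, [X])) ** 2))
        Xs = _center_scale(X)
        Xd = np.column_stack([np.ones(20), Xs])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        resid_ols = float(np.sum((y - Xd @ beta) ** 2))
        assert abs(resid_model - resid_ols) < 1e-6
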