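"""Edge-weighted IoU/BCE losses against scalar double-loop oracles."""

import math

import numpy as np
import pytest

from hardvessel.nn import Tensor
from hardvessel.objective import (
    LossConfig,
    edge_weight_map,
    total_loss,
    weighted_bce_loss,
    weighted_iou_loss,
)


# ---------------------------------------------------------------------------
# independent oracles: naive per-pixel double loops
# ---------------------------------------------------------------------------

def oracle_edge_weights(G, window, gamma, border="valid"):
    h, w = G.shape
    r = window // 2
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            acc, cnt = 0.0, 0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w:
                        acc += G[ii, jj]
                        cnt += 1
            mean = acc / cnt if border == "valid" else acc / window**2
            out[i, j] = 1.0 + gamma * abs(mean - G[i, j])
    return out


def oracle_iou(S, G, W):
    num = den = 0.0
    for i in range(S.shape[0]):
        for j in range(S.shape[1]):
            num += W[i, j] * S[i, j] * G[i, j]
            den += W[i, j] * (S[i, j] + G[i, j] - S[i, j] * G[i, j])
    return 1.0 - num / den


def oracle_bce(S, G, W, eps=1e-7):
    num = den = 0.0
    for i in range(S.shape[0]):
        for j in range(S.shape[1]):
            s = min(max(S[i, j], eps), 1.0 - eps)
            num += W[i, j] * (-G[i, j] * math.log(s)
                              - (1.0 - G[i, j]) * math.log(1.0 - s))
            den += W[i, j]
    return num / den


# ---------------------------------------------------------------------------
# edge weight map
# ---------------------------------------------------------------------------

class TestEdgeWeightMap:
    def test_constant_masks_have_unit_weights(self):
        for G in (np.zeros((40, 40)), np.ones((40, 40))):
            w = edge_weight_map(G, 31, 5.0).weights
            np.testing.assert_allclose(w, 1.0, atol=1e-12)

    def test_single_pixel_center_weight(self):
        # a lone vessel pixel at the centre of a 41×41 zero mask: the 31×31
        # window holds 961 pixels, local mean 1/961, |mean − 1| = 960/961
        G = np.zeros((41, 41))
        G[20, 20] = 1.0
        w = edge_weight_map(G, 31, 5.0, border="zero").weights
        assert w[20, 20] == pytest.approx(1 + 5 * (1 - 1 / 961), abs=1e-9)

    @pytest.mark.parametrize("border", ["valid", "zero"])
    def test_matches_brute_force_scan_including_borders(self, border):
        rng = np.random.default_rng(5)
        for _ in range(3):
            G = (rng.random((24, 20)) > 0.7).astype(float)
            got = edge_weight_map(G, 7, 5.0, border=border).weights
            np.testing.assert_allclose(
                got, oracle_edge_weights(G, 7, 5.0, border), atol=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            edge_weight_map(np.zeros((8, 8)), window=30)

    def test_weights_bounded_by_one_plus_gamma(self, rng):
        G = (rng.random((32, 32)) > 0.8).astype(float)
        w = edge_weight_map(G, 31, 5.0).weights
        assert (w >= 1.0).all() and (w <= 6.0).all()


# ---------------------------------------------------------------------------
# loss terms
# ---------------------------------------------------------------------------

class TestAnalyticValues:
    def test_perfect_prediction_zeroes_both_losses(self, rng):
        G = (rng.random((12, 12)) > 0.7).astype(float)
        W = edge_weight_map(G, 7, 5.0)
        assert weighted_iou_loss(G.copy(), G, W) == pytest.approx(0.0)
        assert weighted_bce_loss(G.copy(), G, W) < 1e-6

    def test_inverted_prediction_maximises_iou_loss(self, rng):
        G = (rng.random((12, 12)) > 0.7).astype(float)
        W = edge_weight_map(G, 7, 5.0)
        assert weighted_iou_loss(1.0 - G, G, W) == pytest.approx(1.0)

    def test_uniform_half_probability_gives_ln2(self, rng):
        G = (rng.random((10, 10)) > 0.5).astype(float)
        S = np.full((10, 10), 0.5)
        assert weighted_bce_loss(S, G) == pytest.approx(math.log(2),
                                                        abs=1e-9)

    def test_worked_2x2_iou_case(self):
        S = np.array([[1.0, 0.0], [0.0, 0.0]])
        G = np.array([[1.0, 1.0], [0.0, 0.0]])
        assert weighted_iou_loss(S, G) == 0.5

    def test_worked_1x2_weighted_bce_case(self):
        S = np.array([[0.9, 0.2]])
        G = np.array([[1.0, 0.0]])
        W = np.array([[2.0, 1.0]])
        expected = (2 * -math.log(0.9) + 1 * -math.log(0.8)) / 3
        assert weighted_bce_loss(S, G, W) == pytest.approx(expected,
                                                           abs=1e-9)


class TestOracleEquivalence:
    def test_vectorized_losses_match_double_loop(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            S = rng.random((16, 16))
            G = (rng.random((16, 16)) > 0.75).astype(float)
            gamma = rng.uniform(0.0, 8.0)
            W = edge_weight_map(G, 7, gamma)
            assert weighted_iou_loss(S, G, W) == pytest.approx(
                oracle_iou(S, G, W.weights), abs=1e-6)
            assert weighted_bce_loss(S, G, W) == pytest.approx(
                oracle_bce(S, G, W.weights), abs=1e-6)

    def test_tensor_path_agrees_with_numpy_path(self, rng):
        S = rng.random((1, 1, 16, 16))
        G = (rng.random((1, 1, 16, 16)) > 0.8).astype(float)
        W = edge_weight_map(G, 7, 5.0)
        t_iou = weighted_iou_loss(Tensor(S), G, W)
        t_bce = weighted_bce_loss(Tensor(S), G, W)
        assert t_iou.item() == pytest.approx(weighted_iou_loss(S, G, W),
                                             abs=1e-12)
        assert t_bce.item() == pytest.approx(weighted_bce_loss(S, G, W),
                                             abs=1e-12)


class TestTotalLoss:
    def test_lambda_projection(self, rng):
        S = rng.random((14, 14))
        G = (rng.random((14, 14)) > 0.8).astype(float)
        cfg = LossConfig(lambda1=1.0, lambda2=0.0)
        loss, bd = total_loss(S, G, cfg)
        W = edge_weight_map(G, cfg.window, cfg.gamma)
        assert loss == pytest.approx(weighted_iou_loss(S, G, W), abs=1e-12)
        assert bd["iou"] == pytest.approx(loss)

    def test_perfect_prediction_near_zero(self, rng):
        G = (rng.random((14, 14)) > 0.8).astype(float)
        loss, _ = total_loss(G.copy(), G)
        assert loss < 1e-6

    def test_composite_matches_term_sum(self, rng):
        S = rng.random((16, 16))
        G = (rng.random((16, 16)) > 0.8).astype(float)
        cfg = LossConfig()
        loss, bd = total_loss(S, G, cfg)
        assert loss == pytest.approx(0.5 * bd["iou"] + 0.5 * bd["bce"],
                                     abs=1e-12)

    def test_deep_supervision_sums_per_map(self, rng):
        S = rng.random((8, 8))
        G = (rng.random((8, 8)) > 0.8).astype(float)
        single, _ = total_loss(S, G)
        double, _ = total_loss([S, S], G)
        assert double == pytest.approx(2 * single, abs=1e-12)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            total_loss(rng.random((8, 8)), np.zeros((9, 8)))


class TestProperties:
    def test_losses_nonnegative_and_iou_bounded(self, rng):
        for _ in range(20):
            S = rng.random((10, 10))
            G = (rng.random((10, 10)) > 0.7).astype(float)
            W = edge_weight_map(G, 7, 5.0)
            iou = weighted_iou_loss(S, G, W)
            bce = weighted_bce_loss(S, G, W)
            assert 0.0 <= iou <= 1.0 and bce >= 0.0

    def test_moving_toward_target_never_increases_loss(self, rng):
        S = rng.random((12, 12))
        G = (rng.random((12, 12)) > 0.7).astype(float)
        W = edge_weight_map(G, 7, 5.0)
        closer = S + 0.3 * (G - S)
        assert weighted_iou_loss(closer, G, W) <= weighted_iou_loss(S, G, W)
        assert weighted_bce_loss(closer, G, W) <= weighted_bce_loss(S, G, W)

    def test_gradients_finite_on_clamped_domain(self, rng):
        S = Tensor(rng.random((1, 1, 12, 12)), requires_grad=True)
        G = (rng.random((1, 1, 12, 12)) > 0.7).astype(float)
        loss, _ = total_loss(S, G)
        loss.backward()
        assert np.isfinite(S.grad).all()

    def test_gradient_matches_finite_differences(self, rng):
        S0 = rng.random((6, 6)) * 0.8 + 0.1
        G = (rng.random((6, 6)) > 0.6).astype(float)
        t = Tensor(S0.copy(), requires_grad=True)
        loss, _ = total_loss(t, G)
        loss.backward()
        eps = 1e-6
        for idx in [(0, 0), (2, 3), (5, 5)]:
            pert = S0.copy()
            pert[idx] += eps
            hi, _ = total_loss(pert, G)
            pert[idx] -= 2 * eps
            lo, _ = total_loss(pert, G)
            assert t.grad[idx] == pytest.approx((hi - lo) / (2 * eps),
                                                rel=1e-4, abs=1e-6)
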