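"""Pixel-importance-balanced weight map and weighted cross-entropy."""

import numpy as np
import pytest

from vesselseg import (
    PIBWeightParams,
    compute_pib_weights,
    pib_loss,
    total_supervised_loss,
)
from vesselseg.nn import Tensor

from conftest import numerical_gradient

RNG = np.random.default_rng(7)


def weight_oracle(mask, radius=2, vs=-0.04, vi=2.0, bs=0.04, bi=1.0):
    """Nested-loop reference: count vessel pixels in the centred box."""
    h, w = mask.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            num = 0
            for p in range(i - radius, i + radius + 1):
                for q in range(j - radius, j + radius + 1):
                    if 0 <= p < h and 0 <= q < w:
                        num += mask[p, q]
            out[i, j] = vs * num + vi if mask[i, j] == 1 else bs * num + bi
    return out


def bce_oracle(pred, mask, weights, eps=1e-7):
    """Per-pixel loop of weighted binary cross-entropy (mean reduction)."""
    total = 0.0
    p = np.clip(pred, eps, 1 - eps)
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] == 1:
                total -= weights[i, j] * np.log(p[i, j])
            else:
                total -= weights[i, j] * np.log(1 - p[i, j])
    return total / mask.size


def test_all_background_weights_are_exactly_one():
    w = compute_pib_weights(np.zeros((10, 10), dtype=np.uint8))
    assert np.array_equal(w, np.ones((10, 10)))


def test_all_vessel_5x5_center_weight_is_one():
    w = compute_pib_weights(np.ones((5, 5), dtype=np.uint8))
    # centre pixel counts all 25 neighbours including itself: -25*0.04+2 = 1
    assert w[2, 2] == pytest.approx(1.0, abs=1e-12)


def test_isolated_vessel_pixel_weights():
    mask = np.zeros((11, 11), dtype=np.uint8)
    mask[5, 5] = 1
    w = compute_pib_weights(mask)
    assert w[5, 5] == pytest.approx(1.96, abs=1e-12)  # num=1 (itself)
    for ni, nj in ((4, 5), (6, 5), (5, 4), (5, 6)):
        assert w[ni, nj] == pytest.approx(1.04, abs=1e-12)
    assert w[0, 0] == pytest.approx(1.0, abs=1e-12)  # far background


def test_vectorised_weights_match_nested_loop_oracle():
    for k in range(100):
        mask = (np.random.default_rng(k).random((16, 16)) < 0.3).astype(np.uint8)
        got = compute_pib_weights(mask)
        np.testing.assert_allclose(got, weight_oracle(mask), atol=1e-12)


def test_weight_bounds_for_default_constants():
    for k in range(30):
        mask = (np.random.default_rng(200 + k).random((20, 20)) < 0.5).astype(np.uint8)
        w = compute_pib_weights(mask)
        assert w.min() >= 1.0 - 1e-12
        assert w.max() <= 1.96 + 1e-12


def test_vessel_weight_decreases_with_neighbourhood_count():
    # a 1-px line's pixels outweigh the interior of a thick band
    thin = np.zeros((11, 11), dtype=np.uint8)
    thin[5, :] = 1
    thick = np.zeros((11, 11), dtype=np.uint8)
    thick[2:9, :] = 1
    w_thin = compute_pib_weights(thin)[5, 5]
    w_thick = compute_pib_weights(thick)[5, 5]
    assert w_thin > w_thick
    # background weight increases with nearby vessel count
    w_near = compute_pib_weights(thin)[6, 5]
    w_far = compute_pib_weights(thin)[9, 5]
    assert w_near > w_far == 1.0


def test_custom_box_radius_is_honoured():
    mask = np.zeros((9, 9), dtype=np.uint8)
    mask[4, 4] = 1
    params = PIBWeightParams(box_radius=3)
    w = compute_pib_weights(mask, params)
    # neighbour at Chebyshev distance 3 now sees the vessel pixel
    assert w[1, 4] == pytest.approx(1.04, abs=1e-12)


def test_non_binary_mask_rejected():
    with pytest.raises(ValueError):
        compute_pib_weights(np.full((4, 4), 0.5))


def test_unit_weight_loss_equals_plain_cross_entropy():
    mask = (RNG.random((12, 12)) < 0.25).astype(np.uint8)
    pred = RNG.uniform(0.01, 0.99, (12, 12))
    ones = np.ones_like(pred)
    got = pib_loss(pred, mask, weights=ones)
    assert got == pytest.approx(bce_oracle(pred, mask, ones), abs=1e-6)


def test_weighted_loss_matches_per_pixel_loop():
    mask = (RNG.random((10, 10)) < 0.3).astype(np.uint8)
    pred = RNG.uniform(0.01, 0.99, (10, 10))
    w = compute_pib_weights(mask)
    assert pib_loss(pred, mask) == pytest.approx(bce_oracle(pred, mask, w), abs=1e-6)


def test_uniform_half_prediction_closed_form():
    mask = (RNG.random((14, 14)) < 0.2).astype(np.uint8)
    w = compute_pib_weights(mask)
    got = pib_loss(np.full((14, 14), 0.5), mask)
    assert got == pytest.approx(w.mean() * np.log(2.0), rel=1e-9)


def test_perfect_prediction_loss_is_negligible():
    mask = (RNG.random((8, 8)) < 0.3).astype(np.uint8)
    loss = pib_loss(mask.astype(float), mask)
    assert 0.0 <= loss <= -np.log(1 - 1e-7) * 2.0 + 1e-12


def test_sum_reduction_is_mean_times_pixels():
    mask = (RNG.random((6, 6)) < 0.3).astype(np.uint8)
    pred = RNG.uniform(0.1, 0.9, (6, 6))
    assert pib_loss(pred, mask, reduction="sum") == pytest.approx(
        pib_loss(pred, mask, reduction="mean") * 36, rel=1e-9
    )


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        pib_loss(np.zeros((4, 4)) + 0.5, np.zeros((5, 5), dtype=np.uint8))


def test_loss_gradient_matches_finite_differences():
    mask = (RNG.random((8, 8)) < 0.3).astype(np.uint8)
    pred = RNG.uniform(0.05, 0.95, (8, 8))
    t = Tensor(pred, requires_grad=True)
    pib_loss(t, mask).backward()
    num = numerical_gradient(lambda a: pib_loss(a, mask), pred)
    np.testing.assert_allclose(t.grad, num, rtol=1e-4, atol=1e-8)


def test_total_loss_is_main_plus_lambda_aux():
    mask = (RNG.random((8, 8)) < 0.3).astype(np.uint8)
    fine = RNG.uniform(0.1, 0.9, (8, 8))
    coarse = RNG.uniform(0.1, 0.9, (8, 8))
    sup = total_supervised_loss(fine, coarse, mask, lambda_aux=1.0)
    assert sup.total == pytest.approx(sup.loss_main + sup.loss_aux, rel=1e-12)
    assert sup.lambda_aux == 1.0

    no_aux = total_supervised_loss(fine, coarse, mask, lambda_aux=0.0)
    assert no_aux.total == pytest.approx(no_aux.loss_main, rel=1e-12)

    same = total_supervised_loss(fine, fine, mask, lambda_aux=1.0)
    assert same.total == pytest.approx(2 * same.loss_main, rel=1e-12)
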