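"""Loss terms against naive per-pixel loop transcriptions, closed forms,
and numerical gradients."""

import math

import numpy as np
import pytest

import isvseg.losses as L
from isvseg.nn import Tensor

EPS = L.DEFAULT_EPS


def two_channel(y_isv):
    """Build (2, H, W) probability maps with complementary channels."""
    return np.stack([y_isv, 1.0 - y_isv])


# ---------------------------------------------------------------------------
# contour bands
# ---------------------------------------------------------------------------

class TestContourBands:
    def test_centered_square_band_counts(self):
        """A 4x4 square centered in 8x8 with band width 1: the inner band is
        the square's 12-pixel perimeter ring, the outer band its 20-pixel
        8-connected halo — confirmed by scanning all 64 pixels."""
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[2:6, 2:6] = 1
        bands = L.compute_contour_bands(mask, band_width=1)
        assert bands.n_inner == 12
        assert bands.n_outer == 20

        # brute-force neighbourhood scan (8-connected, band width 1)
        inner, outer = set(), set()
        for r in range(8):
            for c in range(8):
                nbrs = [(r + dr, c + dc)
                        for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                        if (dr, dc) != (0, 0)
                        and 0 <= r + dr < 8 and 0 <= c + dc < 8]
                if mask[r, c] and any(mask[nr, nc] == 0 for nr, nc in nbrs):
                    inner.add((r, c))
                if not mask[r, c] and any(mask[nr, nc] == 1 for nr, nc in nbrs):
                    outer.add((r, c))
        assert {tuple(p) for p in np.argwhere(bands.inner)} == inner
        assert {tuple(p) for p in np.argwhere(bands.outer)} == outer

    @pytest.mark.parametrize("mask", [np.zeros((6, 6)), np.ones((6, 6))])
    def test_boundary_free_masks_flagged_empty(self, mask):
        bands = L.compute_contour_bands(mask.astype(np.uint8))
        assert bands.empty and bands.total == 0
        assert bands.n_inner == bands.n_outer == 0

    def test_set_identities_on_random_masks(self, rng):
        for _ in range(10):
            mask = (rng.random((12, 12)) > 0.6).astype(np.uint8)
            bands = L.compute_contour_bands(mask, band_width=2)
            assert not (bands.inner & bands.outer).any()
            assert bands.mu.sum() == bands.total == bands.n_inner + bands.n_outer
            assert not (bands.inner & ~mask.astype(bool)).any()
            assert not (bands.outer & mask.astype(bool)).any()

    def test_band_grows_monotonically_with_width(self, rng):
        mask = (rng.random((16, 16)) > 0.7).astype(np.uint8)
        totals = [L.compute_contour_bands(mask, w).total for w in (1, 2, 4)]
        assert totals[0] <= totals[1] <= totals[2]


# ---------------------------------------------------------------------------
# weighted cross-entropy
# ---------------------------------------------------------------------------

class TestWeightedCrossEntropy:
    def test_uniform_half_is_log_two(self):
        pred = two_channel(np.full((4, 4), 0.5))
        t = np.zeros((4, 4))
        t[1:3, 1:3] = 1
        assert L.weighted_cross_entropy(pred, t).item() == pytest.approx(math.log(2))

    def test_perfect_prediction_hits_clamping_floor(self):
        t = (np.arange(16).reshape(4, 4) % 3 == 0).astype(float)
        pred = two_channel(t)
        assert L.weighted_cross_entropy(pred, t).item() <= -math.log(1 - EPS) + 1e-12

    def test_matches_per_pixel_loop(self, rng):
        t = (rng.random((4, 4)) > 0.5).astype(float)
        y = rng.uniform(0.05, 0.95, (4, 4))
        pos_w = 2.5
        got = L.weighted_cross_entropy(two_channel(y), t, pos_weight=pos_w).item()
        acc = 0.0
        for r in range(4):
            for c in range(4):
                yi = min(max(y[r, c], EPS), 1 - EPS)
                acc += -(pos_w * t[r, c] * math.log(yi)
                         + (1 - t[r, c]) * math.log(1 - yi))
        assert got == pytest.approx(acc / 16, rel=1e-6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            L.weighted_cross_entropy(two_channel(np.zeros((4, 4))), np.zeros((5, 5)))


# ---------------------------------------------------------------------------
# contour-aware loss
# ---------------------------------------------------------------------------

class TestContourAwareLoss:
    def test_perfect_band_prediction_near_zero(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[2:6, 2:6] = 1
        bands = L.compute_contour_bands(mask, band_width=1)
        pred = two_channel(mask.astype(float))
        val = L.contour_aware_loss(pred, mask.astype(float), bands).item()
        assert 0.0 <= val <= 2 * -math.log(1 - EPS) + 1e-12

    def test_matches_loop_transcription(self, rng):
        """Band-restricted class-balanced form: -(|I+|/|I|) sum_{inner} log y
        -(|I-|/|I|) sum_{outer} log(1-y), normalized by |I|."""
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[1:3, 1:3] = 1
        bands = L.compute_contour_bands(mask, band_width=1)
        y = rng.uniform(0.05, 0.95, (4, 4))
        got = L.contour_aware_loss(two_channel(y), mask.astype(float), bands).item()

        inner = {tuple(p) for p in np.argwhere(bands.inner)}
        outer = {tuple(p) for p in np.argwhere(bands.outer)}
        total = len(inner) + len(outer)
        acc = 0.0
        for p in inner:
            acc += -(len(outer) / total) * math.log(y[p])
        for p in outer:
            acc += -(len(inner) / total) * math.log(1 - y[p])
        assert got == pytest.approx(acc / total, rel=1e-6)

    def test_swap_flag_transposes_weights(self, rng):
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[1:3, 1:4] = 1  # asymmetric bands
        bands = L.compute_contour_bands(mask, band_width=1)
        y = rng.uniform(0.1, 0.9, (4, 4))
        a = L.contour_aware_loss(two_channel(y), mask.astype(float), bands).item()
        b = L.contour_aware_loss(two_channel(y), mask.astype(float), bands,
                                 swap_band_weights=True).item()
        assert a != pytest.approx(b)

    def test_empty_bands_fall_back_to_wce(self, rng):
        t = np.zeros((4, 4))
        y = rng.uniform(0.1, 0.9, (4, 4))
        bands = L.compute_contour_bands(t.astype(np.uint8))
        fall = L.contour_aware_loss(two_channel(y), t, bands).item()
        wce = L.weighted_cross_entropy(two_channel(y), t).item()
        assert fall == pytest.approx(wce)

    def test_emphasis_mode_weights_band_double(self, rng):
        mask = np.zeros((6, 6), dtype=np.uint8)
        mask[2:4, 2:4] = 1
        bands = L.compute_contour_bands(mask, band_width=1)
        y = rng.uniform(0.1, 0.9, (6, 6))
        got = L.contour_aware_loss(two_channel(y), mask.astype(float), bands,
                                   mode="emphasis").item()
        acc = 0.0
        for r in range(6):
            for c in range(6):
                w = 1.0 + bands.mu[r, c]
                acc += -w * (mask[r, c] * math.log(y[r, c])
                             + (1 - mask[r, c]) * math.log(1 - y[r, c]))
        assert got == pytest.approx(acc / 36, rel=1e-6)


# ---------------------------------------------------------------------------
# shape-constraint loss
# ---------------------------------------------------------------------------

class TestShapeConstraintLoss:
    def test_ground_truth_hits_clamping_floor(self):
        t = (np.arange(9).reshape(3, 3) % 2).astype(float)
        val = L.shape_constraint_loss(two_channel(t), t).item()
        assert 0.0 <= val <= 2 * EPS + 1e-12

    def test_uniform_half_is_log_two(self):
        t = (np.arange(9).reshape(3, 3) % 2).astype(float)
        pred = np.full((2, 3, 3), 0.5)
        assert L.shape_constraint_loss(pred, t).item() == pytest.approx(math.log(2))

    def test_matches_loop_transcription(self, rng):
        t = (rng.random((3, 3)) > 0.5).astype(float)
        pred = rng.uniform(0.05, 0.95, (2, 3, 3))
        got = L.shape_constraint_loss(pred, t).item()
        acc = 0.0
        for r in range(3):
            for c in range(3):
                y0, y1 = pred[0, r, c], pred[1, r, c]
                u = (y0 if t[r, c] == 1 else y1) / (y0 + y1)
                acc += -math.log(u)
        assert got == pytest.approx(acc / 9, rel=1e-6)

    def test_strictly_decreasing_along_blend_to_truth(self):
        t = np.zeros((6, 6))
        t[2:4, 1:5] = 1
        target_maps = two_channel(t)
        vals = []
        for alpha in (0.0, 0.25, 0.5, 0.75, 1.0):
            pred = (1 - alpha) * 0.5 + alpha * target_maps
            vals.append(L.shape_constraint_loss(pred, t).item())
        assert all(b < a for a, b in zip(vals, vals[1:]))


# ---------------------------------------------------------------------------
# combined objective and gradients
# ---------------------------------------------------------------------------

class TestTotalObjective:
    def test_full_objective_is_contour_plus_shape(self, rng):
        t = np.zeros((6, 6))
        t[2:4, 2:5] = 1
        bands = L.compute_contour_bands(t.astype(np.uint8), 1)
        pred = rng.uniform(0.1, 0.9, (2, 6, 6))
        br = L.total_objective(pred, t, bands, terms="s+c")
        assert br.L == pytest.approx(br.L_c + br.L_s)
        assert not br.contour_fallback

    @pytest.mark.parametrize("arm", L.LOSS_ARMS)
    def test_every_arm_finite_and_nonnegative(self, arm, rng):
        t = (rng.random((5, 5)) > 0.5).astype(float)
        bands = L.compute_contour_bands(t.astype(np.uint8), 1)
        pred = rng.uniform(0.01, 0.99, (2, 5, 5))
        br = L.total_objective(pred, t, bands, terms=arm)
        for v in (br.L, br.L_wce, br.L_c, br.L_s):
            assert np.isfinite(v) and v >= 0

    def test_default_weight_decay_value(self):
        assert L.DEFAULT_WEIGHT_DECAY == 5e-4

    def test_perfect_prediction_near_zero(self):
        t = np.zeros((6, 6))
        t[2:4, 2:4] = 1
        bands = L.compute_contour_bands(t.astype(np.uint8), 1)
        br = L.total_objective(two_channel(t), t, bands, terms="s+c")
        assert br.L <= 4 * EPS + 4 * -math.log(1 - EPS)


def test_autodiff_gradients_match_central_differences(rng):
    """d(total objective)/d(prediction) on a 2x3x3 map agrees with numeric
    central differences to 1e-4 relative."""
    t = np.array([[1.0, 0, 0], [0, 1, 1], [0, 0, 1]])
    bands = L.compute_contour_bands(t.astype(np.uint8), 1)
    pred_data = rng.uniform(0.15, 0.85, (2, 3, 3))

    pred = Tensor(pred_data.copy(), requires_grad=True)
    br = L.total_objective(pred, t, bands, terms="s+c")
    br.tensor.backward()

    for idx in np.ndindex(2, 3, 3):
        eps = 1e-6
        orig = pred_data[idx]
        pred_data[idx] = orig + eps
        hi = L.total_objective(pred_data, t, bands, terms="s+c").L
        pred_data[idx] = orig - eps
        lo = L.total_objective(pred_data, t, bands, terms="s+c").L
        pred_data[idx] = orig
        num = (hi - lo) / (2 * eps)
        assert pred.grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)
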