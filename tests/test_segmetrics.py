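import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoforecast import segmetrics as sm
from phenoforecast import synthgen as sg


def brute_force_counts(pred, truth):
    """Independent per-pixel loop oracle."""
    tp = fp = fn = tn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, t = bool(pred[i, j]), bool(truth[i, j])
            if p and t:
                tp += 1
            elif p and not t:
                fp += 1
            elif not p and t:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


class TestConfusionAndScores:
    def test_perfect_prediction(self, rng):
        truth = rng.random((16, 16)) < 0.4
        c = sm.confusion_counts(truth, truth)
        n = int(truth.sum())
        assert (c.tp, c.fp, c.fn) == (n, 0, 0)
        assert sm.seg_score(truth, truth).fbeta == 1.0

    def test_all_background_prediction(self, rng):
        truth = rng.random((16, 16)) < 0.4
        c = sm.confusion_counts(np.zeros_like(truth), truth)
        assert c.fn == int(truth.sum()) and c.tp == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_counts_match_pixel_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.random((16, 16)) < 0.5
        truth = rng.random((16, 16)) < 0.5
        c = sm.confusion_counts(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == brute_force_counts(pred, truth)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            sm.confusion_counts(np.zeros((4, 4)), np.zeros((4, 5)))

    def test_iou_examples(self):
        a = np.zeros((4, 4), bool)
        a[1:3, 1:3] = True
        assert sm.iou(a, a) == 1.0
        b = np.zeros((4, 4), bool)
        b[0, 0] = True
        a2 = np.zeros((4, 4), bool)
        a2[3, 3] = True
        assert sm.iou(a2, b) == 0.0
        shifted = np.roll(a, 1, axis=1)  # overlap 2, union 6
        assert sm.iou(a, shifted) == pytest.approx(1 / 3)

    def test_empty_vs_empty_iou_is_one(self):
        z = np.zeros((4, 4), bool)
        assert sm.iou(z, z) == 1.0

    def test_fbeta_direct_substitution(self):
        # TP=2, FP=2, FN=2 -> P=R=F1=0.5
        pred = np.array([[1, 1, 1, 1, 0, 0]], dtype=bool)
        truth = np.array([[1, 1, 0, 0, 1, 1]], dtype=bool)
        s = sm.seg_score(pred, truth)
        assert (s.precision, s.recall, s.fbeta) == (0.5, 0.5, 0.5)

    def test_beta_zero_limit_is_precision(self):
        pred = np.array([[1, 1, 1, 0]], dtype=bool)
        truth = np.array([[1, 0, 1, 1]], dtype=bool)
        s = sm.seg_score(pred, truth, beta=0.0)
        assert s.fbeta == pytest.approx(s.precision)

    def test_f1_iou_identity(self, rng):
        for _ in range(20):
            pred = rng.random((12, 12)) < 0.5
            truth = rng.random((12, 12)) < 0.5
            s = sm.seg_score(pred, truth)
            assert s.fbeta == pytest.approx(2 * s.iou / (1 + s.iou), abs=1e-12)


class TestLosses:
    def test_exact_prediction_zero_dice(self):
        truth = np.array([[1, 0], [0, 1]], bool)
        assert sm.dice_loss(truth.astype(float), truth) == 0.0

    def test_inverted_prediction_unit_dice(self):
        truth = np.array([[1, 0], [0, 1]], bool)
        assert sm.dice_loss(1.0 - truth.astype(float), truth) == 1.0

    def test_uniform_half_probability_hand_computed(self):
        # 4 px, half foreground, p=0.5: soft TP=FP=FN=1 -> loss 0.5
        truth = np.array([[1, 1, 0, 0]], bool)
        prob = np.full((1, 4), 0.5)
        assert sm.dice_loss(prob, truth) == pytest.approx(0.5)

    def test_probabilities_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            sm.dice_loss(np.array([[1.2]]), np.array([[1]], bool))

    def test_focal_single_pixel_direct_evaluation(self):
        # y=1, p=0.5, alpha=0.25, gamma=2: 0.25 * 0.25 * ln 2
        truth = np.array([[1]], bool)
        prob = np.array([[0.5]])
        expected = 0.25 * 0.25 * np.log(2.0)
        assert sm.focal_loss(prob, truth) == pytest.approx(expected, rel=1e-9)

    def test_confident_correct_prediction_vanishing_focal(self):
        truth = np.array([[1, 0]], bool)
        prob = np.array([[1.0, 0.0]])
        assert sm.focal_loss(prob, truth) < 1e-10

    def test_unbalanced_focal_reduces_to_cross_entropy(self, rng):
        truth = rng.random((8, 8)) < 0.5
        prob = rng.uniform(0.05, 0.95, (8, 8))
        fl = sm.focal_loss(prob, truth, alpha=1.0, gamma=0.0, balanced=False)
        y = truth.astype(float)
        ce = float(np.mean(-(y * np.log(prob) + (1 - y) * np.log(1 - prob))))
        assert fl == pytest.approx(ce, abs=1e-10)

    def test_combined_is_exactly_additive(self, rng):
        truth = rng.random((8, 8)) < 0.4
        prob = rng.uniform(0.0, 1.0, (8, 8))
        cfg = sm.LossConfig()
        total = sm.combined_loss(prob, truth, cfg)
        parts = sm.dice_loss(prob, truth, cfg.beta) + sm.focal_loss(
            prob, truth, cfg.alpha, cfg.gamma
        )
        assert total == pytest.approx(parts, abs=1e-12)

    def test_loss_gradient_matches_finite_differences(self, rng):
        prob = rng.uniform(0.05, 0.95, 25)
        truth = rng.integers(0, 2, 25).astype(bool)
        grad = sm.combined_loss_grad(prob, truth)
        eps = 1e-6
        for i in range(0, 25, 5):
            up, dn = prob.copy(), prob.copy()
            up[i] += eps
            dn[i] -= eps
            num = (sm.combined_loss(up, truth) - sm.combined_loss(dn, truth)) / (2 * eps)
            assert grad[i] == pytest.approx(num, abs=1e-7)

    def test_invalid_loss_config_rejected(self):
        with pytest.raises(ValueError):
            sm.LossConfig(alpha=0.0)
        with pytest.raises(ValueError):
            sm.LossConfig(gamma=-1.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10_000))
def test_metric_bounds_property(seed):
    """IoU, P, R, F all in [0,1]; dice loss in [0,1]; focal >= 0."""
    rng = np.random.default_rng(seed)
    pred = rng.random((8, 8)) < rng.random()
    truth = rng.random((8, 8)) < rng.random()
    prob = rng.uniform(0, 1, (8, 8))
    s = sm.seg_score(pred, truth)
    for v in (s.iou, s.precision, s.recall, s.fbeta):
        assert 0.0 <= v <= 1.0
    assert 0.0 <= sm.dice_loss(prob, truth) <= 1.0
    assert sm.focal_loss(prob, truth) >= 0.0


class TestAugment:
    @pytest.fixture
    def pair(self):
        return sg.render_rosette(sg.RosetteSpec(target_pa=300, image_size=48, seed=1))

    def test_horizontal_flip_is_involution(self, pair):
        img, mask = pair
        (img1, m1), = sm.augment(img, mask, ops=("flip_h",))
        (img2, m2), = sm.augment(img1, m1, ops=("flip_h",))
        assert np.array_equal(img2, img) and np.array_equal(m2, mask)

    def test_photometric_ops_leave_mask_unchanged(self, pair):
        img, mask = pair
        for op in ("blur", "sharpen"):
            (_, m), = sm.augment(img, mask, ops=(op,))
            assert np.array_equal(m, mask)

    def test_pad_then_center_crop_restores_original(self, pair):
        img, mask = pair
        (img_p, m_p), = sm.augment(img, mask, ops=("pad",), seed=0)
        p = (img_p.shape[0] - img.shape[0]) // 2
        assert np.array_equal(img_p[p:-p, p:-p], img)
        assert np.array_equal(m_p[p:-p, p:-p], mask)

    def test_unknown_op_rejected(self, pair):
        with pytest.raises(ValueError, match="unknown"):
            sm.augment(*pair, ops=("rotate",))


class TestRefineMask:
    def test_clean_mask_unchanged(self):
        mask = np.zeros((32, 32), bool)
        mask[8:24, 8:24] = True
        assert np.array_equal(sm.refine_mask(mask, min_area=3, max_hole=3), mask)

    def test_speckles_removed_exactly(self):
        mask = np.zeros((32, 32), bool)
        mask[8:24, 8:24] = True
        speckled = mask.copy()
        for y, x in [(0, 0), (2, 30), (30, 2), (29, 29), (0, 15)]:
            speckled[y, x] = True
        refined = sm.refine_mask(speckled, min_area=3, max_hole=3)
        assert refined.sum() == speckled.sum() - 5
        assert np.array_equal(refined, mask)

    def test_idempotent(self, rng):
        prob = rng.uniform(0, 1, (32, 32))
        once = sm.refine_mask(prob)
        twice = sm.refine_mask(once)
        assert np.array_equal(once, twice)


class TestTrainSegmenter:
    @pytest.fixture(scope="class")
    def pairs(self):
        return sg.generate_training_pairs(24, image_size=48, seed=9)

    def test_zero_epochs_returns_untrained_model_empty_log(self, pairs):
        model, log = sm.train_segmenter(pairs, epochs=0, seed=0)
        assert log == []
        assert isinstance(model, sm.TinySegmenter)

    def test_same_seed_reproduces_log(self, pairs):
        _, log1 = sm.train_segmenter(pairs, epochs=3, seed=4)
        _, log2 = sm.train_segmenter(pairs, epochs=3, seed=4)
        assert [(s.iou, s.fbeta) for s in log1] == [(s.iou, s.fbeta) for s in log2]

    def test_training_beats_untrained_model(self, pairs):
        untrained, _ = sm.train_segmenter(pairs, epochs=0, seed=4)
        trained, log = sm.train_segmenter(pairs, epochs=5, seed=4)
        img, mask = pairs[0]
        before = sm.seg_score(untrained.predict(img), mask).fbeta
        after = sm.seg_score(trained.predict(img), mask).fbeta
        assert after > before
        assert log[-1].fbeta > 0.5

    def test_too_few_pairs_rejected(self, pairs):
        with pytest.raises(ValueError, match="10"):
            sm.train_segmenter(pairs[:5], epochs=1, seed=0)

    def test_unknown_learner_rejected(self, pairs):
        with pytest.raises(ValueError, match="learner_spec"):
            sm.train_segmenter(pairs, epochs=1, learner_spec="resnet")
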