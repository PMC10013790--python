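import itertools

import numpy as np
import pytest

from wheatseg.errors import InputError
from wheatseg.metrics import (
    binarize,
    dice,
    evaluate,
    gaussian_noise,
    iou,
    majority_vote,
    sepia,
    tta_predict,
)


class TestBinarize:
    def test_threshold_is_inclusive(self):
        assert binarize(np.full((3, 3), 0.5), 0.5).all()

    def test_high_threshold_zeroes_everything(self):
        assert not binarize(np.full((3, 3), 0.9), 0.999).any()

    def test_idempotent(self):
        p = np.random.default_rng(0).random((5, 5))
        once = binarize(p)
        assert np.array_equal(binarize(once.astype(float)), once)

    def test_invalid_threshold(self):
        with pytest.raises(InputError):
            binarize(np.zeros((2, 2)), 1.5)


class TestOverlapScores:
    def test_identical_nonempty_masks(self):
        m = np.eye(4, dtype=np.uint8)
        assert dice(m, m) == 1.0
        assert iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), np.uint8)
        b = np.zeros((4, 4), np.uint8)
        a[0, 0] = 1
        b[3, 3] = 1
        assert dice(a, b) == 0.0 and iou(a, b) == 0.0

    def test_worked_examples(self):
        a = np.zeros((4, 4), np.uint8)
        b = np.zeros((4, 4), np.uint8)
        a[0, :4] = 1  # |O| = 4
        b[0, 2:4] = 1
        b[1, 2:4] = 1  # |E| = 4, overlap 2
        assert dice(a, b) == pytest.approx(0.5)  # 2*2/8
        assert iou(a, b) == pytest.approx(1 / 3)  # 2/6

    def test_both_empty_convention(self):
        z = np.zeros((3, 3), np.uint8)
        assert dice(z, z) == 1.0 and iou(z, z) == 1.0

    def test_dice_iou_functional_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a = (rng.random((6, 6)) > 0.5).astype(np.uint8)
            b = (rng.random((6, 6)) > 0.5).astype(np.uint8)
            d, j = dice(a, b), iou(a, b)
            assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(InputError):
            dice(np.zeros((2, 2)), np.zeros((3, 3)))


class TestMajorityVote:
    def test_matches_bruteforce_count(self):
        rng = np.random.default_rng(2)
        masks = [(rng.random((7, 7)) > 0.5).astype(np.uint8) for _ in range(3)]
        vote = majority_vote(masks)
        brute = np.zeros((7, 7), np.uint8)
        for r in range(7):
            for c in range(7):
                brute[r, c] = 1 if sum(m[r, c] for m in masks) >= 2 else 0
        assert np.array_equal(vote, brute)

    def test_injected_votes(self):
        one = np.ones((1, 1), np.uint8)
        zero = np.zeros((1, 1), np.uint8)
        assert majority_vote([one, one, zero])[0, 0] == 1
        assert majority_vote([zero, zero, one])[0, 0] == 0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        masks = [(rng.random((5, 5)) > 0.5).astype(np.uint8) for _ in range(3)]
        ref = majority_vote(masks)
        for perm in itertools.permutations(masks):
            assert np.array_equal(majority_vote(list(perm)), ref)

    def test_even_count_rejected(self):
        with pytest.raises(InputError):
            majority_vote([np.zeros((2, 2))] * 2)


class _ConstantModel:
    """Predicts the same probability map regardless of input."""

    def __init__(self, probs):
        self._probs = probs

    def predict_proba(self, X):
        return [self._probs[: x.shape[0], : x.shape[1]] for x in X]


class TestTTA:
    def test_photometric_variants_change_image_not_shape(self):
        img = np.random.default_rng(4).random((8, 8, 3)).astype(np.float32)
        sep = sepia(img)
        noisy = gaussian_noise(img, 0.05)
        assert sep.shape == img.shape and noisy.shape == img.shape
        assert not np.array_equal(sep, img) and not np.array_equal(noisy, img)
        assert sep.min() >= 0 and sep.max() <= 1

    def test_constant_model_tta_equals_plain(self):
        rng = np.random.default_rng(5)
        probs = rng.random((8, 8))
        model = _ConstantModel(probs)
        img = rng.random((8, 8, 3)).astype(np.float32)
        assert np.array_equal(tta_predict(model, img), binarize(probs))

    def test_variant_failure_names_variant(self):
        class Broken:
            def predict_proba(self, X):
                if X[0].mean() > 0.9:  # sepia pushes values up
                    raise ValueError("boom")
                return [np.full(X[0].shape[:2], 0.4)]

        img = np.full((4, 4, 3), 0.8, dtype=np.float32)
        with pytest.raises(RuntimeError, match="sepia"):
            tta_predict(Broken(), img)

    def test_tta_on_real_network(self, tiny_net):
        img = np.random.default_rng(6).random((32, 32, 3)).astype(np.float32)
        mask = tta_predict(tiny_net, img, rng_seed=1)
        assert mask.shape == (32, 32)
        assert set(np.unique(mask)).issubset({0, 1})


class TestEvaluate:
    def _manifest(self, tmp_path, preds_truth):
        from wheatseg import imgio
        from wheatseg.manifest import DatasetManifest, make_row

        rows = []
        (tmp_path / "images").mkdir(exist_ok=True)
        (tmp_path / "masks").mkdir(exist_ok=True)
        for i, (domain, truth) in enumerate(preds_truth):
            img = np.random.default_rng(i).random((8, 8, 3)).astype(np.float32)
            imgio.save_image(tmp_path / "images" / f"{i}.png", img)
            imgio.save_mask(tmp_path / "masks" / f"{i}.png", truth)
            rows.append(
                make_row(id=f"im{i}", image_path=f"images/{i}.png", mask_path=f"masks/{i}.png",
                         split="test", stage="eval", domain=domain, seed=i)
            )
        return DatasetManifest.from_rows(rows, root=tmp_path)

    def test_perfect_prediction_scores_one(self, tmp_path):
        truth = np.ones((8, 8), np.uint8)
        man = self._manifest(tmp_path, [("a", truth)])
        model = _ConstantModel(np.full((8, 8), 0.99))
        _, summary = evaluate(model, man)
        assert summary["dice"] == 1.0 and summary["iou"] == 1.0

    def test_macro_average_convention(self, tmp_path):
        # one perfect image, one fully missed: macro mean 0.5
        hit = np.ones((8, 8), np.uint8)
        miss = np.zeros((8, 8), np.uint8)
        man = self._manifest(tmp_path, [("a", hit), ("a", miss)])
        model = _ConstantModel(np.full((8, 8), 0.99))
        df, summary = evaluate(model, man)
        assert summary["dice"] == pytest.approx(0.5)
        assert len(df) == 2

    def test_per_domain_grouping(self, tmp_path):
        truth = np.ones((8, 8), np.uint8)
        man = self._manifest(tmp_path, [("a", truth), ("a", truth), ("b", truth), ("b", truth)])
        model = _ConstantModel(np.full((8, 8), 0.99))
        _, summary = evaluate(model, man, group_by="domain")
        assert set(summary["per_group"]) == {"a", "b"}
        assert all(v["n"] == 2 for v in summary["per_group"].values())

    def test_missing_mask_raises_with_record(self, tmp_path):
        truth = np.ones((8, 8), np.uint8)
        man = self._manifest(tmp_path, [("a", truth)])
        (tmp_path / "masks" / "0.png").unlink()
        with pytest.raises(InputError, match="im0"):
            evaluate(_ConstantModel(np.full((8, 8), 0.9)), man)
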