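import numpy as np
import pytest

from wheatseg import imgio
from wheatseg.adapt import (
    StageConfig,
    generate_pseudo_labels,
    load_dataset,
    rotations_dataset,
    run_pipeline,
    train_stage,
)
from wheatseg.errors import ConfigError, InputError
from wheatseg.framestore import Frame
from wheatseg.manifest import DatasetManifest, make_row
from wheatseg.model import UNetSegmenter


@pytest.fixture(scope="module")
def annotated_pair():
    rng = np.random.default_rng(0)
    image = rng.random((24, 24, 3)).astype(np.float32)
    mask = np.zeros((24, 24), np.uint8)
    mask[8:14, 5:12] = 1
    return image, mask


class TestRotationsDataset:
    def test_emits_360_records(self, tmp_path, annotated_pair):
        man = rotations_dataset(*annotated_pair, tmp_path)
        assert len(man) == 360
        man.validate_files()

    def test_degree_zero_byte_identical(self, tmp_path, annotated_pair):
        image, mask = annotated_pair
        rotations_dataset(image, mask, tmp_path)
        imgio.save_image(tmp_path / "ref_img.png", image)
        imgio.save_mask(tmp_path / "ref_mask.png", mask)
        assert (tmp_path / "images" / "rot_000.png").read_bytes() == (tmp_path / "ref_img.png").read_bytes()
        assert (tmp_path / "masks" / "rot_000.png").read_bytes() == (tmp_path / "ref_mask.png").read_bytes()

    def test_half_turn_preserves_mask_area(self, tmp_path, annotated_pair):
        image, mask = annotated_pair
        rotations_dataset(image, mask, tmp_path)
        m180 = imgio.load_mask(tmp_path / "masks" / "rot_180.png")
        assert m180.sum() == mask.sum()
        assert np.array_equal(m180, mask[::-1, ::-1])

    def test_rotated_canvas_expands(self, tmp_path, annotated_pair):
        image, mask = annotated_pair
        rotations_dataset(image, mask, tmp_path)
        m45 = imgio.load_mask(tmp_path / "masks" / "rot_045.png")
        assert m45.shape[0] > mask.shape[0]

    def test_shape_mismatch_rejected(self, tmp_path):
        with pytest.raises(InputError):
            rotations_dataset(np.zeros((8, 8, 3)), np.zeros((9, 9)), tmp_path)


class _ConstLogitNet:
    """Stand-in model producing a constant logit everywhere."""

    divisor = 1

    def __init__(self, logit):
        self._logit = logit

    def forward(self, x, train=False):
        return np.full(x.shape[:3], self._logit, dtype=np.float32)


class TestPseudoLabels:
    def _frames(self, n=4):
        rng = np.random.default_rng(1)
        return [Frame(index=i, image=rng.random((16, 16, 3)).astype(np.float32), clip_id="u")
                for i in range(n)]

    def test_saturated_negative_model_gives_empty_masks(self, tmp_path):
        man = generate_pseudo_labels(_ConstLogitNet(-40.0), self._frames(), tmp_path)
        for p in man.mask_paths():
            assert not imgio.load_mask(p).any()

    def test_record_count(self, tmp_path):
        man = generate_pseudo_labels(_ConstLogitNet(0.2), self._frames(5), tmp_path)
        assert len(man) == 5

    def test_roundtrip_equals_recomputed_prediction(self, tmp_path, tiny_net):
        frames = [Frame(index=0, image=np.random.default_rng(2).random((32, 32, 3)).astype(np.float32))]
        man = generate_pseudo_labels(tiny_net, frames, tmp_path, threshold=0.5)
        from wheatseg.metrics import binarize
        from wheatseg.nn import predict_probs

        stored = imgio.load_mask(man.mask_paths()[0])
        recomputed = binarize(predict_probs(tiny_net, frames[0].image), 0.5)
        assert np.array_equal(stored, recomputed)

    def test_empty_frames_raise(self, tmp_path):
        with pytest.raises(InputError):
            generate_pseudo_labels(_ConstLogitNet(0.0), [], tmp_path)


def _tiny_manifest(tmp_path, n=6, hw=(16, 16), name="data"):
    root = tmp_path / name
    (root / "images").mkdir(parents=True)
    (root / "masks").mkdir(parents=True)
    rng = np.random.default_rng(0)
    rows = []
    for i in range(n):
        img = rng.random((*hw, 3)).astype(np.float32)
        mask = (img[..., 0] > 0.6).astype(np.uint8)
        imgio.save_image(root / "images" / f"{i}.png", img)
        imgio.save_mask(root / "masks" / f"{i}.png", mask)
        rows.append(make_row(id=f"r{i}", image_path=f"images/{i}.png", mask_path=f"masks/{i}.png"))
    man = DatasetManifest.from_rows(rows, root=root)
    man.save()
    return man


class TestTrainStage:
    def test_single_epoch_selects_epoch_one(self, tmp_path):
        man = _tiny_manifest(tmp_path)
        cfg = StageConfig(stage_id="S", train_manifest=man, val_manifest=man, epochs=1,
                          out_dir=tmp_path / "ckpt")
        ckpt = train_stage(cfg)
        assert ckpt.selected_epoch == 1
        assert len(ckpt.history) == 1

    def test_selected_epoch_attains_min_val_loss(self, tmp_path):
        man = _tiny_manifest(tmp_path)
        cfg = StageConfig(stage_id="S", train_manifest=man, val_manifest=man, epochs=4,
                          out_dir=tmp_path / "ckpt")
        ckpt = train_stage(cfg)
        vals = [h["val_loss"] for h in ckpt.history]
        assert ckpt.val_loss == min(vals)
        assert vals[ckpt.selected_epoch - 1] == min(vals)

    def test_injected_history_argmin(self, monkeypatch, tmp_path):
        # force a known val-loss sequence; the middle epoch must be selected
        man = _tiny_manifest(tmp_path)
        seq = iter([0.5, 0.3, 0.4])
        monkeypatch.setattr(UNetSegmenter, "_eval_loss", lambda self, *a, **k: next(seq))
        cfg = StageConfig(stage_id="S", train_manifest=man, val_manifest=man, epochs=3,
                          out_dir=tmp_path / "ckpt")
        ckpt = train_stage(cfg)
        assert ckpt.selected_epoch == 2
        assert ckpt.val_loss == 0.3

    def test_seeded_determinism(self, tmp_path):
        man = _tiny_manifest(tmp_path)
        cfg = dict(stage_id="S", train_manifest=man, val_manifest=man, epochs=2, seed=5)
        a = train_stage(StageConfig(**cfg, out_dir=tmp_path / "a"))
        b = train_stage(StageConfig(**cfg, out_dir=tmp_path / "b"))
        assert a.val_loss == b.val_loss
        assert a.history == b.history

    def test_empty_manifest_rejected(self, tmp_path):
        import pandas as pd

        from wheatseg.manifest import MANIFEST_COLUMNS

        empty = DatasetManifest(records=pd.DataFrame(columns=MANIFEST_COLUMNS), root=tmp_path)
        with pytest.raises(InputError, match="empty"):
            train_stage(StageConfig(stage_id="S", train_manifest=empty, val_manifest=empty))

    def test_init_from_checkpoint_changes_start(self, tmp_path):
        man = _tiny_manifest(tmp_path)
        first = train_stage(StageConfig(stage_id="S", train_manifest=man, val_manifest=man,
                                        epochs=1, out_dir=tmp_path / "a"))
        resumed = train_stage(StageConfig(stage_id="D", train_manifest=man, val_manifest=man,
                                          epochs=1, init_from=first.weights_path,
                                          out_dir=tmp_path / "b"))
        scratch = train_stage(StageConfig(stage_id="D", train_manifest=man, val_manifest=man,
                                          epochs=1, out_dir=tmp_path / "c"))
        assert resumed.val_loss != scratch.val_loss


class TestPipelineValidation:
    def test_missing_stage_dataset_names_stage(self, tmp_path):
        man = _tiny_manifest(tmp_path)
        path = str(man.root / "manifest.csv")
        config = {
            "workdir": str(tmp_path),
            "stages": {
                "S": {"train_manifest": path, "val_manifest": path},
                "D": {"train_manifest": path, "val_manifest": path},
                "P": {"unlabeled_dir": str(man.root / "images"), "val_dir": str(man.root / "images")},
                "G": {"train_manifest": str(tmp_path / "missing.csv"), "val_manifest": path},
                "baseline": {"train_manifest": path, "val_manifest": path},
            },
        }
        with pytest.raises(ConfigError, match="G"):
            run_pipeline(config)

    def test_missing_stage_key_rejected(self, tmp_path):
        with pytest.raises(ConfigError, match="S"):
            run_pipeline({"workdir": str(tmp_path), "stages": {}})

    def test_unknown_keys_rejected_before_any_work(self, tmp_path):
        with pytest.raises(ConfigError, match="typo_key"):
            run_pipeline({"workdir": str(tmp_path), "typo_key": 1, "stages": {}})
        with pytest.raises(ConfigError, match="S"):
            run_pipeline({"workdir": str(tmp_path), "stages": {"S": {"epochz": 3}}})


def test_load_dataset_subsampling(tmp_path):
    man = _tiny_manifest(tmp_path, n=10)
    X, y = load_dataset(man, max_images=4, seed=1)
    assert len(X) == 4 and len(y) == 4
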