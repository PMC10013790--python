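import numpy as np
import pytest

from wheatseg.cutouts import Cutout, CutoutSet
from wheatseg.errors import InputError
from wheatseg.framestore import Frame
from wheatseg.synthesis import (
    AugmentParams,
    augment_cutout,
    compose,
    sample_for_seed,
    synthesize_dataset,
)


def _single_cutout_bank(kind, size=2, value=0.9):
    patch = np.full((size, size, 3), value, dtype=np.float32)
    fp = np.ones((size, size), dtype=np.uint8)
    c = Cutout(patch=patch, footprint=fp, bbox=(0, 0, size, size), kind=kind, cutout_id=f"{kind}-0")
    return CutoutSet(cutouts=[c], kind=kind)


def _background(hw=(12, 12)):
    return Frame(index=0, image=np.zeros((*hw, 3), dtype=np.float32), clip_id="bg")


def oracle_mask(placements, shape):
    """Independent re-rasterization: union of real footprints, clipped."""
    H, W = shape
    m = np.zeros(shape, dtype=np.uint8)
    for pl in placements:
        if pl.kind != "real":
            continue
        fp = pl.footprint
        r0, c0 = pl.top_left
        rr0, cc0 = max(r0, 0), max(c0, 0)
        rr1, cc1 = min(r0 + fp.shape[0], H), min(c0 + fp.shape[1], W)
        if rr0 >= rr1 or cc0 >= cc1:
            continue
        m[rr0:rr1, cc0:cc1] |= fp[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]
    return m


class TestAugmentCutout:
    def test_identity_params_bit_for_bit(self, banks):
        real, _ = banks
        out = augment_cutout(real[0], rng_seed=5, params=AugmentParams.identity())
        assert np.array_equal(out.patch, real[0].patch)
        assert np.array_equal(out.footprint, real[0].footprint)

    def test_horizontal_flip_is_involution(self, banks):
        real, _ = banks
        flip_only = AugmentParams(
            hflip=True, vflip=False, rotation=(0, 0), scale=(1, 1), elastic_prob=0
        )
        # find a seed whose sampled transform actually flips
        src = real[0]
        for seed in range(20):
            once = augment_cutout(src, seed, flip_only)
            if not np.array_equal(once.footprint, src.footprint) or not np.array_equal(
                once.patch, src.patch
            ):
                assert np.array_equal(once.patch[:, ::-1], src.patch)
                return
        pytest.fail("no flipping transform sampled in 20 seeds")

    def test_scale_doubles_footprint_area(self):
        patch = np.random.default_rng(0).random((2, 2, 3)).astype(np.float32)
        c = Cutout(patch=patch, footprint=np.ones((2, 2), np.uint8), bbox=(0, 0, 2, 2), kind="real")
        params = AugmentParams(hflip=False, vflip=False, rotation=(0, 0), scale=(2.0, 2.0), elastic_prob=0)
        out = augment_cutout(c, rng_seed=1, params=params)
        # independent geometry oracle: exact 2x upsampling of a full square
        expected = np.kron(c.footprint, np.ones((2, 2), np.uint8))
        assert 12 <= out.footprint.sum() <= 20
        assert out.footprint.sum() == expected.sum()

    def test_seeded_determinism(self, banks):
        real, _ = banks
        a = augment_cutout(real[1], rng_seed=42)
        b = augment_cutout(real[1], rng_seed=42)
        assert np.array_equal(a.patch, b.patch) and np.array_equal(a.footprint, b.footprint)


class TestCompose:
    def test_zero_placements_returns_background(self, backgrounds):
        empty = CutoutSet(cutouts=[], kind="real")
        empty_f = CutoutSet(cutouts=[], kind="fake")
        s = compose(backgrounds[0], empty, empty_f, rng_seed=0, n_range=(0, 0), color_aug=False)
        assert np.array_equal(s.image, backgrounds[0].image)
        assert not s.mask.any()

    def test_single_forced_placement_mask(self):
        bg = _background()
        real = _single_cutout_bank("real")
        fake = _single_cutout_bank("fake", value=0.1)
        s = compose(bg, real, fake, rng_seed=3, n_range=(1, 1), color_aug=False,
                    aug_params=AugmentParams.identity())
        n_real = sum(1 for p in s.placements if p.kind == "real")
        assert n_real == 1
        pl = [p for p in s.placements if p.kind == "real"][0]
        expected = oracle_mask([pl], s.mask.shape)
        assert np.array_equal(s.mask, expected)
        assert 1 <= s.mask.sum() <= 4  # 2x2 footprint possibly clipped

    def test_mask_equals_oracle_rerasterization(self, backgrounds, banks):
        real, fake = banks
        for seed in range(10):
            s = compose(backgrounds[0], real, fake, rng_seed=seed, n_range=(3, 12))
            assert np.array_equal(s.mask, oracle_mask(s.placements, s.mask.shape))

    def test_fake_only_pixels_never_masked(self, backgrounds, banks):
        real, fake = banks
        s = compose(backgrounds[0], real, fake, rng_seed=5, n_range=(5, 15))
        real_union = oracle_mask(s.placements, s.mask.shape)
        assert not s.mask[real_union == 0].any()

    def test_color_aug_never_touches_mask(self, backgrounds, banks):
        real, fake = banks
        a = compose(backgrounds[0], real, fake, rng_seed=9, n_range=(3, 10), color_aug=True)
        b = compose(backgrounds[0], real, fake, rng_seed=9, n_range=(3, 10), color_aug=False)
        assert np.array_equal(a.mask, b.mask)
        assert not np.array_equal(a.image, b.image)

    def test_empty_bank_with_nonzero_count_raises(self, backgrounds):
        empty = CutoutSet(cutouts=[], kind="real")
        fake = _single_cutout_bank("fake")
        with pytest.raises(InputError):
            compose(backgrounds[0], empty, fake, rng_seed=0, n_range=(2, 2))

    def test_counts_within_requested_range(self, backgrounds, banks):
        real, fake = banks
        s = compose(backgrounds[0], real, fake, rng_seed=1, n_range=(4, 9))
        kinds = [p.kind for p in s.placements]
        assert 4 <= kinds.count("real") <= 9
        assert 4 <= kinds.count("fake") <= 9
        # painter's order: all fakes recorded before all reals
        assert kinds == sorted(kinds)


class TestSynthesizeDataset:
    def test_record_count_and_files(self, tmp_path, backgrounds, banks):
        real, fake = banks
        man = synthesize_dataset(backgrounds, real, fake, tmp_path, n_images=3, base_seed=5,
                                 n_range=(2, 6))
        assert len(man) == 3
        man.validate_files()

    def test_deterministic_masks_for_same_seed(self, tmp_path, backgrounds, banks):
        real, fake = banks
        synthesize_dataset(backgrounds, real, fake, tmp_path / "a", n_images=2, base_seed=7, n_range=(2, 6))
        synthesize_dataset(backgrounds, real, fake, tmp_path / "b", n_images=2, base_seed=7, n_range=(2, 6))
        for name in ["s_00000.png", "s_00001.png"]:
            a = (tmp_path / "a" / "masks" / name).read_bytes()
            b = (tmp_path / "b" / "masks" / name).read_bytes()
            assert a == b

    def test_zero_images(self, tmp_path, backgrounds, banks):
        real, fake = banks
        man = synthesize_dataset(backgrounds, real, fake, tmp_path, n_images=0)
        assert len(man) == 0

    def test_sample_reproducible_from_seed(self, backgrounds, banks):
        real, fake = banks
        a = sample_for_seed(backgrounds, real, fake, seed=123, n_range=(3, 8))
        b = sample_for_seed(backgrounds, real, fake, seed=123, n_range=(3, 8))
        assert np.array_equal(a.image, b.image) and np.array_equal(a.mask, b.mask)
        assert a.background_id == b.background_id
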