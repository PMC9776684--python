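import numpy as np
import pytest

from pathomsi.errors import ConfigError, ValidationError
from pathomsi.segmentation import (
    SegTrainConfig, StubSegModel, UNet, binarize, build_unet, compute_iou,
    compute_iou_averaged, crossvalidate_segmentation, downsample_mask,
    predict_heatmap, tile_image, train_segmentation,
)
from pathomsi.synthetic import generate_scene, render_he
from pathomsi.types import BinaryMask, Heatmap, WsiImage


class TestTileImage:
    def test_non_overlapping_cover(self):
        img = np.zeros((512, 512, 3))
        tiles = tile_image(img, None, 256, 256)
        assert [t.origin for t in tiles] == [(0, 0), (0, 256), (256, 0), (256, 256)]

    def test_overlapping_cover(self):
        tiles = tile_image(np.zeros((512, 512, 3)), None, 256, 128)
        assert len(tiles) == 9

    def test_tile_larger_than_image_padded(self):
        tiles = tile_image(np.zeros((100, 80, 3)), np.zeros((100, 80), bool), 128, 64)
        assert len(tiles) == 1
        (t,) = tiles
        assert t.image.shape == (128, 128, 3) and t.padding == (28, 48)
        assert t.mask.shape == (128, 128)

    def test_edge_anchored_extra_tile(self):
        tiles = tile_image(np.zeros((300, 300, 3)), None, 128, 128)
        origins = {t.origin for t in tiles}
        assert (172, 172) in origins  # anchored at the far edge, no padding


class TestUNet:
    def test_forward_softmax_probabilities(self, rng):
        cfg = SegTrainConfig(tile_size=32, base_width=4)
        model = build_unet(cfg)
        x = rng.uniform(size=(1, 32, 32, 3))
        p = model.predict_proba(x)
        assert p.shape == (1, 32, 32, 2)
        np.testing.assert_allclose(p.sum(axis=3), 1.0, atol=1e-12)

    def test_zero_input_finite(self):
        model = UNet(depth=2, base_width=4, seed=0)
        p = model.predict_proba(np.zeros((1, 16, 16, 3)))
        assert np.isfinite(p).all()

    def test_deterministic_forward(self, rng):
        model = UNet(depth=2, base_width=4, seed=3)
        x = rng.uniform(size=(2, 16, 16, 3))
        np.testing.assert_array_equal(model.predict_proba(x), model.predict_proba(x))

    def test_indivisible_tile_rejected(self):
        with pytest.raises(ConfigError):
            build_unet(SegTrainConfig(tile_size=60, stride=30))

    def test_state_round_trip(self, rng):
        a = UNet(depth=2, base_width=4, seed=1)
        b = UNet(depth=2, base_width=4, seed=2)
        b.set_state(a.get_state())
        x = rng.uniform(size=(1, 16, 16, 3))
        np.testing.assert_array_equal(a.predict_proba(x), b.predict_proba(x))


class TestPredictHeatmap:
    def _image(self, h=100, w=90):
        return WsiImage(pixels=np.full((h, w, 3), 200, dtype=np.uint8), section_id="s")

    def test_constant_stub_gives_uniform_heatmap(self):
        hm = predict_heatmap(StubSegModel(0.7), self._image(), 64, 32, downsample=1)
        assert hm.values.shape == (100, 90)
        np.testing.assert_allclose(hm.values, 0.7)

    def test_stride_independent_for_stub(self):
        a = predict_heatmap(StubSegModel(0.42), self._image(), 64, 64, downsample=1)
        b = predict_heatmap(StubSegModel(0.42), self._image(), 64, 32, downsample=1)
        np.testing.assert_allclose(a.values, b.values)

    def test_values_within_unit_interval(self, rng):
        model = UNet(depth=2, base_width=4, seed=5)
        img = WsiImage(pixels=rng.integers(0, 255, (70, 70, 3)).astype(np.uint8))
        hm = predict_heatmap(model, img, 32, 16, downsample=1)
        assert hm.values.min() >= 0 and hm.values.max() <= 1


class TestBinarize:
    def test_uniform_above_threshold(self):
        hm = Heatmap(values=np.full((5, 5), 0.7))
        assert binarize(hm, 0.5).values.all()

    def test_threshold_above_one_gives_empty(self):
        hm = Heatmap(values=np.full((5, 5), 1.0))
        assert not binarize(hm, 1.1).values.any()

    def test_matches_pixelwise_oracle_and_tie_is_tumor(self, rng):
        vals = rng.uniform(size=(20, 20))
        vals[0, 0] = 0.5
        hm = Heatmap(values=vals)
        out = binarize(hm, 0.5)
        np.testing.assert_array_equal(out.values, vals >= 0.5)
        assert out.values[0, 0]


class TestComputeIou:
    def test_identical_masks(self, rng):
        v = rng.uniform(size=(10, 10)) > 0.5
        assert compute_iou(BinaryMask(v), BinaryMask(v.copy())) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool); a[0] = True
        b = np.zeros((4, 4), bool); b[2] = True
        assert compute_iou(BinaryMask(a), BinaryMask(b)) == 0.0

    def test_half_overlap_is_one_third(self):
        a = np.zeros((8, 8), bool); a[:, :4] = True   # left half
        b = np.zeros((8, 8), bool); b[:4, :] = True   # top half
        assert compute_iou(BinaryMask(a), BinaryMask(b)) == pytest.approx(1 / 3)

    def test_both_empty_defined_as_one(self):
        z = BinaryMask(np.zeros((3, 3), bool))
        assert compute_iou(z, BinaryMask(np.zeros((3, 3), bool))) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compute_iou(BinaryMask(np.zeros((3, 3), bool)), BinaryMask(np.zeros((4, 4), bool)))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_counting_oracle(self, seed):
        r = np.random.default_rng(seed)
        a = r.uniform(size=(12, 9)) > r.uniform(0.2, 0.8)
        b = r.uniform(size=(12, 9)) > r.uniform(0.2, 0.8)
        inter = sum(1 for i in range(12) for j in range(9) if a[i, j] and b[i, j])
        union = sum(1 for i in range(12) for j in range(9) if a[i, j] or b[i, j])
        oracle = inter / union if union else 1.0
        assert compute_iou(BinaryMask(a), BinaryMask(b)) == pytest.approx(oracle)

    def test_class_averaged_variant(self):
        a = np.zeros((4, 4), bool); a[:2] = True
        b = np.zeros((4, 4), bool); b[:2] = True
        assert compute_iou_averaged(BinaryMask(a), BinaryMask(b)) == 1.0


def _tiny_sections(seeds, diagnosis="ADC"):
    out = []
    for s in seeds:
        scene = generate_scene(shape=(128, 128), n_tumor_regions=2, seed=s,
                               diagnosis=diagnosis, confounder_rate=0.0)
        out.append(render_he(scene, seed=s + 1))
    return out


TINY_CFG = SegTrainConfig(tile_size=32, stride=32, epochs=2, repetitions=2,
                          downsample=4, base_width=4, tiles_per_epoch=8, seed=11)


@pytest.fixture(scope="module")
def trained():
    train = _tiny_sections([1, 2])
    val = _tiny_sections([3])
    return train_segmentation(train, val, TINY_CFG)


class TestTrainSegmentation:
    def test_selected_checkpoint_is_history_max(self, trained):
        model, hist = trained
        best = hist["best"]
        all_ious = [v for rep in hist["repetitions"] for v in rep]
        assert best["val_iou"] == pytest.approx(max(all_ious))
        assert hist["repetitions"][best["repetition"]][best["epoch"]] == best["val_iou"]

    def test_history_shape(self, trained):
        _, hist = trained
        assert len(hist["repetitions"]) == 2
        assert all(len(r) == 2 for r in hist["repetitions"])

    def test_fixed_seed_reproducible(self, trained):
        _, hist1 = trained
        train = _tiny_sections([1, 2])
        val = _tiny_sections([3])
        _, hist2 = train_segmentation(train, val, TINY_CFG)
        assert hist1["repetitions"] == hist2["repetitions"]

    def test_single_repetition_best_epoch_only(self):
        import dataclasses

        cfg = dataclasses.replace(TINY_CFG, repetitions=1)
        _, hist = train_segmentation(_tiny_sections([1]), _tiny_sections([3]), cfg)
        assert len(hist["repetitions"]) == 1
        assert hist["best"]["repetition"] == 0

    def test_empty_split_rejected(self):
        with pytest.raises(ValidationError):
            train_segmentation([], _tiny_sections([3]), TINY_CFG)


class TestCrossvalidate:
    def test_group_model_bijection_and_disjointness(self):
        groups = {1: _tiny_sections([1]), 2: _tiny_sections([2], "SqCC"), 3: _tiny_sections([3])}
        models, group_map, hists = crossvalidate_segmentation(groups, TINY_CFG)
        assert sorted(models) == ["Seg1", "Seg2", "Seg3"]
        assert sorted(group_map.values()) == [1, 2, 3]
        assert len(hists) == 3

    def test_wrong_group_count_rejected(self):
        with pytest.raises(ValidationError):
            crossvalidate_segmentation({1: _tiny_sections([1]), 2: _tiny_sections([2])}, TINY_CFG)

    def test_overlapping_groups_rejected(self):
        shared = _tiny_sections([5])
        groups = {1: shared, 2: shared, 3: _tiny_sections([3])}
        with pytest.raises(ValidationError):
            crossvalidate_segmentation(groups, TINY_CFG)


def test_downsample_mask_majority():
    v = np.zeros((4, 4), bool)
    v[:2, :2] = True  # one full block
    v[0, 2] = True    # quarter of another block
    out = downsample_mask(v, 2)
    assert out[0, 0] and not out[0, 1]
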