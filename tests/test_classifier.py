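import numpy as np
import pytest

from pathomsi.classifier import (
    IsotopeNet1d, SpecTrainConfig, StubSpecModel, assemble_training_variants,
    build_eval_datasets, build_isotopenet, predict_spectra,
    train_spectrum_classifier,
)
from pathomsi.errors import ConfigError, ValidationError
from pathomsi.register import AffineTransform2D, transfer_mask_to_spots
from pathomsi.types import ADC, SQCC, BinaryMask, MsiDataset


def _toy_spectra(n_per_class, length=120, seed=0):
    """Two classes that differ in which channels carry Gaussian peaks."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    grid = np.arange(length)
    for label, centers in ((ADC, (20, 60)), (SQCC, (40, 90))):
        for _ in range(n_per_class):
            spec = np.zeros(length)
            for c in centers:
                spec += np.exp(-((grid - c) ** 2) / (2 * 2.0**2))
            spec += rng.normal(0, 0.1, length)
            xs.append(spec)
            ys.append(label)
    return np.array(xs), ys


class TestBuildIsotopenet:
    def test_forward_probabilities(self, rng):
        model = build_isotopenet(100, SpecTrainConfig(channels=4))
        p = model.predict_proba(rng.normal(size=(3, 100)))
        assert p.shape == (3, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_spectrum_finite(self):
        model = build_isotopenet(64, SpecTrainConfig(channels=4))
        assert np.isfinite(model.predict_proba(np.zeros((1, 64)))).all()

    def test_batch_permutation_equivariance(self, rng):
        model = build_isotopenet(50, SpecTrainConfig(channels=4))
        x = rng.normal(size=(6, 50))
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            model.predict_proba(x)[perm], model.predict_proba(x[perm]), atol=1e-12
        )

    def test_too_short_spectrum_rejected(self):
        with pytest.raises(ConfigError):
            IsotopeNet1d(3, channels=4)


@pytest.fixture(scope="module")
def trained():
    xt, yt = _toy_spectra(40, seed=1)
    xv, yv = _toy_spectra(20, seed=2)
    cfg = SpecTrainConfig(epochs=6, repetitions=2, channels=4, batch_size=16, seed=3)
    model, hist = train_spectrum_classifier(xt, yt, xv, yv, cfg)
    return model, hist, (xv, yv)


class TestTraining:
    def test_learns_position_coded_classes(self, trained):
        _, hist, _ = trained
        assert hist["best"]["val_bacc"] >= 0.9

    def test_best_checkpoint_equals_history_max(self, trained):
        _, hist, _ = trained
        all_b = [v for rep in hist["repetitions"] for v in rep]
        assert hist["best"]["val_bacc"] == pytest.approx(max(all_b))

    def test_reproducible_history(self, trained):
        _, hist, _ = trained
        xt, yt = _toy_spectra(40, seed=1)
        xv, yv = _toy_spectra(20, seed=2)
        cfg = SpecTrainConfig(epochs=6, repetitions=2, channels=4, batch_size=16, seed=3)
        _, hist2 = train_spectrum_classifier(xt, yt, xv, yv, cfg)
        assert hist["repetitions"] == hist2["repetitions"]

    def test_beats_label_shuffled_control(self, trained):
        # a single shuffled control can break symmetry along the cluster
        # direction with a random sign, so the control is averaged over
        # several independent shuffles; the large validation set keeps
        # best-epoch selection from inflating it further
        xv, yv = _toy_spectra(100, seed=8)
        xt, yt = _toy_spectra(40, seed=1)
        cfg = SpecTrainConfig(epochs=6, repetitions=1, channels=4, batch_size=16, seed=4)
        _, hist_real = train_spectrum_classifier(xt, yt, xv, yv, cfg)
        controls = []
        for k in range(4):
            rng = np.random.default_rng(9 + k)
            cfg_k = SpecTrainConfig(epochs=6, repetitions=1, channels=4,
                                    batch_size=16, seed=4 + k)
            _, hist_s = train_spectrum_classifier(
                xt, list(rng.permutation(yt)), xv, yv, cfg_k)
            controls.append(hist_s["best"]["val_bacc"])
        assert hist_real["best"]["val_bacc"] - np.mean(controls) >= 0.3

    def test_single_class_split_rejected(self):
        xt, _ = _toy_spectra(10)
        with pytest.raises(ValidationError, match="training"):
            train_spectrum_classifier(xt, [ADC] * len(xt), xt, [ADC, SQCC] * (len(xt) // 2),
                                      SpecTrainConfig(channels=4))

    def test_single_repetition(self):
        xt, yt = _toy_spectra(15, seed=5)
        cfg = SpecTrainConfig(epochs=2, repetitions=1, channels=4, seed=5)
        _, hist = train_spectrum_classifier(xt, yt, xt, yt, cfg)
        assert len(hist["repetitions"]) == 1


def _dataset(coords, n_channels=8):
    coords = np.asarray(coords)
    return MsiDataset(
        mz_axis=np.arange(n_channels, dtype=float) + 700.0,
        intensities=np.ones((coords.shape[0], n_channels)),
        coords=coords,
        section_id="sec",
    )


class TestPredictSpectra:
    def test_stub_always_adc(self):
        ds = _dataset([[0, 0], [1, 0], [2, 0]])
        preds = predict_spectra(StubSpecModel(0.9), ds)
        assert len(preds) == 3
        assert all(p.label == ADC for p in preds)
        for p in preds:
            p.validate()

    def test_exact_tie_resolves_to_adc(self):
        ds = _dataset([[0, 0], [1, 0]])
        preds = predict_spectra(StubSpecModel(0.5), ds)
        assert all(p.label == ADC for p in preds)

    def test_axis_length_mismatch_rejected(self):
        model = IsotopeNet1d(16, channels=4)
        with pytest.raises(ValidationError):
            predict_spectra(model, _dataset([[0, 0]], n_channels=8))

    def test_trained_model_on_marker_spectra(self):
        xt, yt = _toy_spectra(40, seed=1)
        cfg = SpecTrainConfig(epochs=6, repetitions=1, channels=4, batch_size=16, seed=6)
        model, _ = train_spectrum_classifier(xt, yt, xt, yt, cfg)
        xadc, _ = _toy_spectra(30, seed=7)
        ds = MsiDataset(
            mz_axis=np.arange(120, dtype=float) + 700.0,
            intensities=xadc[:30],  # first half are ADC-patterned
            coords=np.array([(i, 0) for i in range(30)]),
        )
        preds = predict_spectra(model, ds)
        assert np.mean([p.label == ADC for p in preds]) >= 0.9


class TestBuildEvalDatasets:
    def _setup(self, seed):
        r = np.random.default_rng(seed)
        coords = np.array([(x, y) for x in range(10) for y in range(10)])
        ds = _dataset(coords)
        t = AffineTransform2D.from_params(scale=4.0)
        ann = BinaryMask(r.uniform(size=(40, 40)) > 0.6)
        seg = BinaryMask(r.uniform(size=(40, 40)) > 0.4)
        return ds, ann, seg, t

    @pytest.mark.parametrize("seed", range(5))
    def test_set_algebra(self, seed):
        ds, ann, seg, t = self._setup(seed)
        sets = build_eval_datasets(ds, ann, seg, t)
        assert not (sets["D2"] & sets["D4"]).any()
        assert (sets["D2"] | sets["D4"]).all()
        np.testing.assert_array_equal(sets["D3"], sets["D2"] & ~sets["D1"])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_membership_oracle(self, seed):
        ds, ann, seg, t = self._setup(seed)
        sets = build_eval_datasets(ds, ann, seg, t)
        d1, _ = transfer_mask_to_spots(ann, t, ds)
        d2, _ = transfer_mask_to_spots(seg, t, ds)
        for i in range(ds.n_spots):
            assert sets["D1"][i] == d1[i]
            assert sets["D2"][i] == d2[i]
            assert sets["D3"][i] == (d2[i] and not d1[i])
            assert sets["D4"][i] == (not d2[i])

    def test_annotation_inside_segmentation(self):
        coords = np.array([(x, y) for x in range(8) for y in range(8)])
        ds = _dataset(coords)
        t = AffineTransform2D.from_params(scale=4.0)
        seg_v = np.zeros((32, 32), bool); seg_v[:16] = True
        ann_v = np.zeros((32, 32), bool); ann_v[:8] = True
        sets = build_eval_datasets(ds, BinaryMask(ann_v), BinaryMask(seg_v), t)
        assert sets["counts"]["D3"] == sets["counts"]["D2"] - sets["counts"]["D1"]

    def test_full_segmentation_empties_d4(self):
        coords = np.array([(x, y) for x in range(8) for y in range(8)])
        ds = _dataset(coords)
        t = AffineTransform2D.from_params(scale=2.0)
        sets = build_eval_datasets(
            ds, BinaryMask(np.zeros((16, 16), bool)), BinaryMask(np.ones((16, 16), bool)), t
        )
        assert sets["counts"]["D4"] == 0


class TestAssembleVariants:
    def _spots(self, n, seed):
        r = np.random.default_rng(seed)
        return r.uniform(size=n) > 0.5

    def test_variant_specs(self):
        group_map = {"Seg1": 1, "Seg2": 2, "Seg3": 3}
        tma = {
            f"tma{i}": {
                "group": (i - 1) % 3 + 1,
                "annotation": self._spots(20, i),
                "seg": {f"Seg{(i - 1) % 3 + 1}": self._spots(20, 10 + i)},
            }
            for i in range(1, 7)
        }
        sections = {
            f"val{i}": {"annotation": self._spots(30, 20 + i), "seg1": self._spots(30, 30 + i)}
            for i in range(1, 3)
        }
        variants = assemble_training_variants(tma, sections, group_map)
        # MALDI1 and MALDI2 share the identical annotation training set
        for sid in tma:
            np.testing.assert_array_equal(
                variants["MALDI1"]["train"][sid], variants["MALDI2"]["train"][sid]
            )
        # MALDI3 uses the mask of the model validated on the sample's group
        for sid, rec in tma.items():
            model = {g: m for m, g in group_map.items()}[rec["group"]]
            np.testing.assert_array_equal(variants["MALDI3"]["train"][sid], rec["seg"][model])
        # validation specs draw only from validation sections
        for v in variants.values():
            assert set(v["val"]) == set(sections)

    def test_missing_group_map_rejected(self):
        with pytest.raises(ValidationError):
            assemble_training_variants({}, {}, {})
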