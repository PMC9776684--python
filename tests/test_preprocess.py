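import numpy as np
import pytest

from pathomsi.errors import ConfigError, ValidationError
from pathomsi.preprocess import (
    PIPELINE_STEPS, PreprocessConfig, baseline_correct, log_transform,
    peptide_resample, profile_normalize, recalibrate, restrict_mz,
    run_pipeline, spatial_smooth,
)
from pathomsi.types import MsiDataset

from conftest import make_dataset


def _ds(mz, intensities, coords=None):
    intensities = np.atleast_2d(intensities)
    if coords is None:
        coords = np.array([(i, 0) for i in range(intensities.shape[0])])
    return MsiDataset(mz_axis=mz, intensities=intensities, coords=coords)


class TestBaselineCorrect:
    def test_zero_baseline_spectrum_unchanged(self):
        mz = np.arange(700.0, 900.0, 0.1)
        spec = np.zeros_like(mz)
        spec += 2.0 * np.exp(-((mz - 800) ** 2) / (2 * 0.1**2))
        out = baseline_correct(_ds(mz, spec), window=50.0)
        np.testing.assert_allclose(out.intensities[0], spec, atol=1e-6)

    def test_constant_spectrum_becomes_zero(self):
        mz = np.arange(700.0, 900.0, 0.1)
        out = baseline_correct(_ds(mz, np.full_like(mz, 3.7)), window=50.0)
        np.testing.assert_allclose(out.intensities[0], 0.0, atol=1e-9)

    def test_peak_on_linear_ramp(self):
        mz = np.arange(700.0, 900.0, 0.1)
        ramp = 0.01 * (mz - 700.0)
        peak = 5.0 * np.exp(-((mz - 800) ** 2) / (2 * 0.1**2))
        out = baseline_correct(_ds(mz, ramp + peak), window=30.0)
        got = out.intensities[0]
        ch = np.argmin(np.abs(mz - 800))
        assert got[ch] == pytest.approx(5.0, rel=0.05)
        # ramp (range 2.0) largely removed away from the peak; the rolling
        # minimum lags by half a window, leaving a small slope-proportional
        # residual that grows at the axis edges
        far = (np.abs(mz - 800) > 5) & (mz > 720) & (mz < 880)
        assert got[far].max() < 0.1 * 2.0

    def test_window_wider_than_axis_rejected(self):
        mz = np.arange(700.0, 710.0, 0.1)
        with pytest.raises(ConfigError):
            baseline_correct(_ds(mz, np.zeros_like(mz)), window=50.0)


class TestRestrictMz:
    def test_default_bounds_700_2700(self):
        mz = np.arange(600.0, 2800.0, 0.5)
        out = restrict_mz(_ds(mz, np.zeros_like(mz)))
        assert out.mz_axis[0] >= 700.0 and out.mz_axis[-1] <= 2700.0
        assert out.mz_axis[0] == 700.0 and out.mz_axis[-1] == 2700.0

    def test_identity_when_axis_inside_bounds(self, small_dataset):
        out = restrict_mz(small_dataset, 600.0, 2800.0)
        np.testing.assert_array_equal(out.mz_axis, small_dataset.mz_axis)
        assert out.n_spots == small_dataset.n_spots

    def test_empty_result_rejected(self):
        mz = np.arange(700.0, 710.0, 0.5)
        with pytest.raises(ValidationError):
            restrict_mz(_ds(mz, np.zeros_like(mz)), 705.21, 705.22)


class TestProfileNormalize:
    def test_scale_invariance(self, small_dataset):
        a = profile_normalize(small_dataset)
        scaled = small_dataset.replace(intensities=small_dataset.intensities * 37.5)
        b = profile_normalize(scaled)
        np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-10)

    def test_all_zero_spectrum_passes_through(self):
        mz = np.arange(700.0, 760.0, 0.1)
        x = np.vstack([np.zeros_like(mz), np.ones_like(mz)])
        out = profile_normalize(_ds(mz, x))
        np.testing.assert_array_equal(out.intensities[0], 0.0)

    def test_two_region_levels_equalized(self):
        rng = np.random.default_rng(0)
        mz = np.arange(700.0, 900.0, 0.1)
        x = rng.uniform(0.5, 1.5, mz.size)
        x[mz < 800] *= 10.0
        out = profile_normalize(_ds(mz, x), window=50.0)
        lo = np.median(out.intensities[0][mz < 790])
        hi = np.median(out.intensities[0][mz > 810])
        assert abs(lo - hi) / hi < 0.10


class TestRecalibrate:
    def test_identical_spots_give_zero_shift(self, small_dataset):
        x = np.tile(small_dataset.intensities[:1], (small_dataset.n_spots, 1))
        ds = small_dataset.replace(intensities=x)
        _, deltas = recalibrate(ds, max_shift=0.25)
        np.testing.assert_array_equal(deltas, 0.0)

    def test_single_spot_self_reference(self):
        ds = make_dataset(n_spots=1)
        out, deltas = recalibrate(ds, max_shift=0.25)
        assert deltas[0] == 0.0
        np.testing.assert_array_equal(out.intensities, ds.intensities)

    def test_injected_shift_recovery(self):
        # shifted copies of one peaky spectrum; the estimator must undo them
        rng = np.random.default_rng(7)
        mz = np.arange(700.0, 1000.0, 0.1)
        base = np.zeros_like(mz)
        for m in np.arange(710, 990, 17.3):
            base += rng.uniform(0.5, 1.5) * np.exp(-((mz - m) ** 2) / (2 * 0.1**2))
        n = 60
        shifts = rng.uniform(-0.2, 0.2, n)
        x = np.stack([
            np.interp(mz - d, mz, base) + rng.normal(0, 0.05, mz.size)
            for d in shifts
        ])
        x = np.clip(x, 0, None)
        ds = _ds(mz, x, coords=np.array([(i % 8, i // 8) for i in range(n)]))
        _, deltas = recalibrate(ds, max_shift=0.25)
        err = np.abs(deltas - shifts)
        assert np.quantile(err, 0.95) <= 0.05

    def test_all_zero_reference_rejected(self):
        mz = np.arange(700.0, 760.0, 0.1)
        ds = _ds(mz, np.zeros((4, mz.size)))
        with pytest.raises(ValidationError):
            recalibrate(ds, max_shift=0.25)

    def test_coarse_axis_rejected(self):
        mz = np.arange(700.0, 760.0, 0.5)
        ds = _ds(mz, np.ones((2, mz.size)))
        with pytest.raises(ConfigError):
            recalibrate(ds, max_shift=0.25)


class TestPeptideResample:
    LAM = 1.000495

    def test_channel_count_by_integer_arithmetic(self):
        # brute-force oracle: integers k with 700 <= k*lambda <= 2700
        ks = [k for k in range(100, 10000) if 700.0 <= k * self.LAM <= 2700.0]
        assert len(ks) == 1999 and ks[0] == 700 and ks[-1] == 2698
        mz = np.arange(700.0, 2700.0 + 0.05, 0.1)
        out = peptide_resample(_ds(mz, np.zeros_like(mz)), self.LAM, 1.0)
        assert out.n_channels == len(ks)
        np.testing.assert_allclose(out.mz_axis, np.array(ks) * self.LAM)

    def test_unit_area_gaussian_lands_in_its_bin(self):
        k = 750
        center = k * self.LAM
        sigma = 0.05
        mz = np.arange(700.0, 800.0, 0.01)
        spec = np.exp(-((mz - center) ** 2) / (2 * sigma**2)) / (sigma * np.sqrt(2 * np.pi))
        out = peptide_resample(_ds(mz, spec), self.LAM, 1.0)
        idx = np.argmin(np.abs(out.mz_axis - center))
        assert out.intensities[0, idx] == pytest.approx(1.0, rel=1e-3)
        rest = np.delete(out.intensities[0], idx)
        assert rest.max() < 0.01

    def test_zero_spectrum_stays_zero(self):
        mz = np.arange(700.0, 800.0, 0.1)
        out = peptide_resample(_ds(mz, np.zeros_like(mz)), self.LAM, 1.0)
        np.testing.assert_array_equal(out.intensities, 0.0)

    def test_mass_conservation_within_one_percent(self):
        rng = np.random.default_rng(3)
        mz = np.arange(700.0, 900.0, 0.05)
        spec = np.zeros_like(mz)
        for m in rng.uniform(720, 880, 20):
            spec += rng.uniform(0.3, 1.0) * np.exp(-((mz - m) ** 2) / (2 * 0.2**2))
        spec += 0.2
        ds_in = _ds(mz, spec)
        out = peptide_resample(ds_in, self.LAM, 1.0)
        total_in = np.trapezoid(spec, mz)
        # compare over the region the output bins actually cover
        lo = out.mz_axis[0] - self.LAM / 2
        hi = out.mz_axis[-1] + self.LAM / 2
        inner = (mz >= lo) & (mz <= hi)
        total_inner = np.trapezoid(spec[inner], mz[inner])
        assert out.intensities.sum() == pytest.approx(total_inner, rel=0.01)
        assert out.intensities.sum() == pytest.approx(total_in, rel=0.02)

    def test_spacing_coarser_than_range_rejected(self):
        mz = np.arange(700.0, 700.5, 0.01)
        with pytest.raises(ConfigError):
            peptide_resample(_ds(mz, np.zeros_like(mz)), 1000.0, 1.0)


class TestSpatialSmooth:
    def test_isolated_spot_unchanged(self):
        mz = np.array([100.0, 101.0])
        ds = MsiDataset(mz_axis=mz, intensities=[[1.0, 2.0]], coords=[[5, 5]])
        out = spatial_smooth(ds, kernel=3)
        np.testing.assert_allclose(out.intensities, [[1.0, 2.0]])

    def test_constant_channel_unchanged(self):
        mz = np.array([100.0, 101.0])
        coords = [[x, y] for x in range(4) for y in range(4)]
        ds = MsiDataset(mz_axis=mz, intensities=np.full((16, 2), 2.5), coords=coords)
        out = spatial_smooth(ds, kernel=3)
        np.testing.assert_allclose(out.intensities, 2.5)

    def test_line_of_three_center_mean(self):
        mz = np.array([100.0])
        ds = MsiDataset(
            mz_axis=mz, intensities=[[0.0], [3.0], [0.0]],
            coords=[[0, 0], [1, 0], [2, 0]],
        )
        out = spatial_smooth(ds, kernel=3)
        assert out.intensities[1, 0] == pytest.approx(1.0)

    def test_even_kernel_rejected(self, small_dataset):
        with pytest.raises(ConfigError):
            spatial_smooth(small_dataset, kernel=4)


class TestLogTransform:
    def test_zero_maps_to_zero(self):
        mz = np.array([100.0, 101.0])
        ds = MsiDataset(mz_axis=mz, intensities=[[0.0, 0.0]], coords=[[0, 0]])
        np.testing.assert_array_equal(log_transform(ds).intensities, 0.0)

    def test_closed_form_value(self):
        mz = np.array([100.0])
        ds = MsiDataset(mz_axis=mz, intensities=[[np.e - 1.0]], coords=[[0, 0]])
        assert log_transform(ds, offset=1.0).intensities[0, 0] == pytest.approx(1.0)

    def test_monotone_on_random_vectors(self, rng):
        mz = np.arange(100.0, 110.0, 1.0)
        x = np.sort(rng.uniform(0, 50, mz.size))
        ds = MsiDataset(mz_axis=mz, intensities=[x], coords=[[0, 0]])
        out = log_transform(ds).intensities[0]
        assert (np.diff(out) >= 0).all()

    def test_negative_input_rejected(self):
        mz = np.array([100.0])
        ds = MsiDataset(mz_axis=mz, intensities=np.array([[-0.1]]), coords=[[0, 0]])
        with pytest.raises(ValidationError):
            log_transform(ds)


class TestRunPipeline:
    def test_step_order_trace(self):
        ds = make_dataset(n_spots=4, lo=650.0, hi=2750.0, step=0.1,
                          peaks=((800.0, 1.0), (1500.0, 0.8)))
        _, trace = run_pipeline(ds, PreprocessConfig())
        assert [t["step"] for t in trace] == list(PIPELINE_STEPS)
        assert trace[3]["n_channels"] == 1999  # after peptide resampling
        assert all(t["n_spots"] == 4 for t in trace)

    def test_second_run_does_not_error(self):
        ds = make_dataset(n_spots=4, lo=650.0, hi=2750.0, step=0.1)
        once, _ = run_pipeline(ds, PreprocessConfig())
        run_pipeline(once, PreprocessConfig(max_shift=2.5))  # smoke: no error

    def test_defaults_from_config(self):
        cfg = PreprocessConfig()
        assert (cfg.mz_lo, cfg.mz_hi) == (700.0, 2700.0)
        assert cfg.resample_spacing == pytest.approx(1.000495)
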