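import numpy as np
import pytest

from morphomsi.spectra import (MSIDataset, match_peaks, mean_spectrum,
                               pick_peaks, read_imzml, rms_normalize,
                               write_imzml, extract_peak_intensities)


def make_ds(intensities, mz=None, coords=None):
    intensities = np.asarray(intensities, dtype=float)
    n, m = intensities.shape
    mz = np.arange(m, dtype=float) + 700.0 if mz is None else mz
    coords = [(i, 0) for i in range(n)] if coords is None else coords
    return MSIDataset(np.array(coords), mz, intensities)


class TestRmsNormalize:
    def test_hand_computed_example(self):
        ds = rms_normalize(make_ds([[3.0, 4.0, 0.0, 0.0]]))
        assert np.allclose(ds.intensities, [[1.2, 1.6, 0.0, 0.0]])
        assert ds.normalization == "rms"

    def test_double_normalization_refused(self):
        ds = rms_normalize(make_ds([[1.0, 2.0]]))
        with pytest.raises(ValueError, match="already normalized"):
            rms_normalize(ds)

    def test_constant_spectrum_becomes_ones(self):
        ds = rms_normalize(make_ds([[5.0, 5.0, 5.0]]))
        assert np.allclose(ds.intensities, 1.0)

    def test_zero_spectrum_left_unchanged_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            ds = rms_normalize(make_ds([[0.0, 0.0], [3.0, 4.0]]))
        assert np.allclose(ds.intensities[0], 0.0)

    def test_every_nonzero_spectrum_has_unit_rms(self, rng):
        raw = rng.uniform(0, 50, size=(20, 300))
        ds = rms_normalize(make_ds(raw))
        rms = np.sqrt(np.mean(ds.intensities**2, axis=1))
        assert np.allclose(rms, 1.0, atol=1e-9)


class TestMeanSpectrum:
    def test_single_spot_identity(self):
        ds = make_ds([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert np.allclose(mean_spectrum(ds, {(0, 0)}), [1, 2, 3])

    def test_two_spots_average(self):
        ds = make_ds([[1.0, 2.0], [3.0, 4.0]])
        assert np.allclose(mean_spectrum(ds, {(0, 0), (1, 0)}), [2.0, 3.0])

    def test_matches_bruteforce_accumulation(self, rng):
        raw = rng.uniform(0, 10, size=(50, 200))
        ds = make_ds(raw)
        spots = {(i, 0) for i in range(0, 50, 2)}
        got = mean_spectrum(ds, spots)
        acc = np.zeros(200)
        for i in sorted(i for i, _ in spots):
            acc += raw[i]
        assert np.allclose(got, acc / len(spots), atol=1e-12)

    def test_order_invariance(self, rng):
        raw = rng.uniform(0, 10, size=(10, 50))
        ds = make_ds(raw)
        spots = [(i, 0) for i in range(10)]
        a = mean_spectrum(ds, spots)
        b = mean_spectrum(ds, list(reversed(spots)))
        assert np.array_equal(a, b)

    def test_empty_and_unknown_spots_rejected(self):
        ds = make_ds([[1.0, 2.0]])
        with pytest.raises(ValueError, match="empty"):
            mean_spectrum(ds, set())
        with pytest.raises(ValueError, match="not present"):
            mean_spectrum(ds, {(9, 9)})


def synth_spectrum(peaks, mz_lo=700.0, mz_hi=900.0, step=0.05, sigma=0.08,
                   baseline=5.0, noise_sd=1.0, seed=0):
    mz = np.arange(mz_lo, mz_hi + step / 2, step)
    y = np.full(mz.size, baseline)
    for center, amp in peaks:
        y += amp * np.exp(-0.5 * ((mz - center) / sigma) ** 2)
    if noise_sd:
        y += np.random.default_rng(seed).normal(0, noise_sd, mz.size)
    return mz, y


class TestPickPeaks:
    def test_recovers_single_planted_peak(self):
        mz, y = synth_spectrum([(812.40, 10.0)], seed=5)
        pl = pick_peaks(mz, y, snr_min=6)
        near = np.abs(pl.mz - 812.40) <= 0.05
        assert near.sum() == 1

    def test_snr_threshold_separates_planted_peaks(self):
        mz, y = synth_spectrum([(780.00, 3.0), (840.00, 8.0)], seed=2)
        pl = pick_peaks(mz, y, snr_min=6)
        assert np.abs(pl.mz - 840.0).min() <= 0.05
        assert not (np.abs(pl.mz - 780.0) <= 0.1).any()

    def test_relative_intensity_rule_excludes_small_peak(self):
        # both peaks far above noise; the small one is 0.2% of the base peak
        mz, y = synth_spectrum([(780.00, 1000.0), (840.00, 2.0)], noise_sd=0.01, seed=3)
        pl = pick_peaks(mz, y, snr_min=6, rel_int_min=0.003)
        assert (np.abs(pl.mz - 780.0) <= 0.05).any()
        assert not (np.abs(pl.mz - 840.0) <= 0.1).any()

    def test_flat_spectrum_yields_empty_list(self):
        mz = np.arange(700.0, 800.0, 0.05)
        assert len(pick_peaks(mz, np.full(mz.size, 3.0))) == 0

    def test_apex_refinement_beats_grid_resolution(self):
        # peak planted off-grid; parabolic refinement should land closer
        # than half a grid step
        mz, y = synth_spectrum([(812.423, 50.0)], noise_sd=0.0)
        pl = pick_peaks(mz, y)
        assert np.abs(pl.mz - 812.423).min() < 0.02


class TestMatchPeaks:
    def test_identical_lists_all_common(self):
        a = np.array([700.0, 800.0, 900.0])
        common, only_a, only_b = match_peaks(a, a.copy(), tol_ppm=20)
        assert len(common) == 3 and not only_a and not only_b

    @pytest.mark.parametrize("b, expect_match", [
        (1000.015, True),    # 15 ppm
        (1000.030, False),   # 30 ppm
    ])
    def test_tolerance_boundary(self, b, expect_match):
        common, *_ = match_peaks(np.array([1000.0]), np.array([b]), tol_ppm=20)
        assert bool(common) is expect_match

    def test_partition_conservation(self, rng):
        for _ in range(20):
            a = np.sort(rng.uniform(700, 1600, size=rng.integers(0, 30)))
            b = np.sort(rng.uniform(700, 1600, size=rng.integers(0, 30)))
            common, only_a, only_b = match_peaks(a, b, tol_ppm=50)
            assert len(common) + len(only_a) == a.size
            assert len(common) + len(only_b) == b.size
            # one-to-one
            assert len({i for i, _ in common}) == len(common)
            assert len({j for _, j in common}) == len(common)


class TestImzmlIO:
    def test_roundtrip_continuous(self, tmp_path, rng):
        ds = make_ds(rng.uniform(0, 100, size=(5, 40)),
                     coords=[(0, 0), (1, 0), (0, 1), (2, 3), (5, 5)])
        path = tmp_path / "a.imzML"
        write_imzml(ds, path)
        back = read_imzml(path)
        assert np.array_equal(back.intensities, ds.intensities)
        assert np.array_equal(back.coordinates, ds.coordinates)

    def test_missing_ibd_named(self, tmp_path, rng):
        ds = make_ds(rng.uniform(0, 1, size=(2, 10)))
        path = tmp_path / "b.imzML"
        write_imzml(ds, path)
        path.with_suffix(".ibd").unlink()
        with pytest.raises(FileNotFoundError, match="ibd"):
            read_imzml(path)

    def test_processed_mode_resampled_to_union_grid(self, tmp_path):
        """Per-spot axes are merged; values interpolate linearly."""
        from pyimzml.ImzMLWriter import ImzMLWriter
        path = tmp_path / "p.imzML"
        axes = [np.array([700.0, 701.0, 702.0]),
                np.array([700.5, 701.5]),
                np.array([700.0, 702.0])]
        vals = [np.array([1.0, 2.0, 3.0]),
                np.array([10.0, 20.0]),
                np.array([5.0, 7.0])]
        with ImzMLWriter(str(path), mode="processed",
                         mz_dtype=np.float64, intensity_dtype=np.float64) as w:
            for i, (mz, v) in enumerate(zip(axes, vals)):
                w.addSpectrum(mz, v, (i + 1, 1, 1))
        ds = read_imzml(path)
        assert ds.resampled
        union = np.unique(np.concatenate(axes))
        assert np.array_equal(ds.mz_axis, union)
        for i, (mz, v) in enumerate(zip(axes, vals)):
            expect = np.interp(union, mz, v, left=0.0, right=0.0)
            assert np.allclose(ds.intensities[i], expect)


class TestExtraction:
    def test_max_in_window_matches_manual(self):
        mz = np.arange(700.0, 710.0, 0.01)
        y = np.zeros((1, mz.size))
        k = np.argmin(np.abs(mz - 705.0))
        y[0, k] = 50.0
        ds = make_ds(y, mz=mz)
        out = extract_peak_intensities(ds, [705.0], tol_ppm=20,
                                       baseline_window_da=5.0)
        assert out[0, 0] == pytest.approx(50.0, rel=0.05)

    def test_feature_window_narrower_than_axis_uses_nearest(self):
        mz = np.arange(700.0, 710.0, 0.5)
        y = np.zeros((1, mz.size))
        y[0, 10] = 9.0   # at 705.0
        ds = make_ds(y, mz=mz)
        out = extract_peak_intensities(ds, [705.1], tol_ppm=20,
                                       baseline_window_da=5.0)
        assert out[0, 0] > 0
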