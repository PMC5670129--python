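import numpy as np
import pytest

import hierclass as hc
from hierclass.ms_preprocess import (
    BinningConfig,
    PeakList,
    Spectrum,
    read_spectrum_text,
)

CFG = BinningConfig(resolution=0.001, mz_min=150.0, mz_max=1000.0)


def gaussian_vector(center_bin, sigma_bins, n=4000, height=1000.0):
    x = np.arange(n, dtype=float)
    return height * np.exp(-0.5 * ((x - center_bin) / sigma_bins) ** 2)


class TestBinning:
    def test_out_of_range_points_discarded(self):
        sp = Spectrum(np.array([149.9, 500.0, 2000.5]), np.array([1.0, 2.0, 3.0]))
        v = hc.bin_spectrum(sp, CFG)
        assert v.sum() == 2.0

    def test_half_open_bin_convention(self):
        sp = Spectrum(np.array([500.0005]), np.array([7.0]))
        v = hc.bin_spectrum(sp, CFG)
        idx = int(np.floor((500.0005 - CFG.mz_min) / CFG.resolution))
        assert v[idx] == 7.0
        # bin [500.000, 500.001) -> center 500.0005
        assert CFG.centers()[idx] == pytest.approx(500.0005)

    def test_same_bin_intensities_summed(self):
        sp = Spectrum(np.array([500.0001, 500.0009]), np.array([1.0, 2.0]))
        assert hc.bin_spectrum(sp, CFG).max() == 3.0

    def test_empty_spectrum_warns_and_zero_fills(self):
        sp = Spectrum(np.array([]), np.array([]))
        with pytest.warns(UserWarning, match="empty"):
            v = hc.bin_spectrum(sp, CFG)
        assert v.shape == (CFG.n_bins,) and not v.any()


class TestDenoise:
    def test_bimodal_threshold_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        v = np.zeros(5000)
        v[rng.choice(5000, 800, replace=False)] = rng.uniform(0.5, 2.0, 800)
        sig = rng.choice(5000, 60, replace=False)
        v[sig] = rng.uniform(500, 2000, 60)
        _, thr = hc.denoise_threshold(v)
        assert 0.5 < thr < 500.0  # between the noise and signal modes

        # exhaustive between-class-variance search over all histogram splits;
        # the chosen threshold must attain the oracle's maximum (thresholds
        # inside an empty-bin gap between modes are equivalent optima)
        logv = np.log(v[v > 0])
        hist, edges = np.histogram(logv, bins=256)
        p = hist / hist.sum()
        mids = 0.5 * (edges[:-1] + edges[1:])

        def bcv_at(split):
            w0, w1 = p[:split].sum(), p[split:].sum()
            if w0 == 0 or w1 == 0:
                return -np.inf
            m0 = (p[:split] * mids[:split]).sum() / w0
            m1 = (p[split:] * mids[split:]).sum() / w1
            return w0 * w1 * (m0 - m1) ** 2

        best = max(bcv_at(i) for i in range(1, 256))
        chosen = int(np.searchsorted(edges[1:-1], np.log(thr)) + 1)
        assert bcv_at(chosen) >= best * (1 - 1e-9)

    def test_all_zero_vector_unchanged(self):
        v = np.zeros(100)
        out, thr = hc.denoise_threshold(v)
        assert thr == 0.0 and not out.any()

    def test_constant_vector_never_partially_corrupted(self):
        v = np.full(50, 3.3)
        out, thr = hc.denoise_threshold(v)
        assert thr <= 3.3
        assert np.all(out == 3.3) or not out.any()


class TestTicSelection:
    def _spectra(self, tics):
        return [
            Spectrum(np.array([500.0]), np.array([t]), replicate=i)
            for i, t in enumerate(tics)
        ]

    def test_top_five_of_eight(self):
        sp = self._spectra([10, 80, 30, 90, 20, 70, 60, 50])
        kept = hc.select_top_tic(sp, k=5)
        assert sorted(s.tic for s in kept) == [50, 60, 70, 80, 90]

    def test_fewer_than_k_kept_with_warning(self):
        sp = self._spectra([1, 2, 3])
        with pytest.warns(UserWarning, match="keeping all"):
            assert len(hc.select_top_tic(sp, k=5)) == 3

    def test_tie_resolved_by_replicate_order(self):
        sp = self._spectra([9, 5, 5, 9, 9])
        kept = hc.select_top_tic(sp, k=4)
        assert [s.replicate for s in kept] == [0, 1, 3, 4]  # earlier 5 wins


class TestPeakDetection:
    def test_single_gaussian_gives_one_apex(self):
        center = 2000
        pl = hc.detect_peaks(gaussian_vector(center, 5), CFG)
        assert len(pl.mz) == 1
        assert abs(pl.mz[0] - CFG.centers()[center]) <= CFG.resolution

    def test_two_gaussians_match_local_maximum_oracle(self):
        from scipy.signal import argrelmax, savgol_filter

        v = gaussian_vector(1000, 5) + gaussian_vector(1020, 5, height=800.0)
        pl = hc.detect_peaks(v, CFG)
        smooth = savgol_filter(v, 11, 3)
        oracle = argrelmax(smooth)[0]
        oracle = oracle[smooth[oracle] > 1.0]
        assert len(pl.mz) == len(oracle) == 2
        got = np.searchsorted(CFG.centers(), pl.mz)
        assert np.abs(np.sort(got) - np.sort(oracle)).max() <= 1

    def test_flat_region_has_no_peaks(self):
        assert len(hc.detect_peaks(np.zeros(500), CFG).mz) == 0

    def test_window_must_fit(self):
        with pytest.raises(ValueError, match="window"):
            hc.detect_peaks(np.zeros(5), CFG, sg_window=11)


class TestKdeMatch:
    def test_jittered_apexes_collapse_to_one_feature(self):
        pls = [
            PeakList(np.array([500.000 + j]), np.array([1.0]))
            for j in (-0.002, 0.0, 0.002)
        ]
        common, aligned = hc.kde_match(pls, bandwidth=0.003)
        assert len(common.mz) == 1
        assert abs(common.mz[0] - 500.000) <= 0.003
        assert aligned.shape == (3, 1) and (aligned > 0).all()

    def test_distant_peaks_stay_separate(self):
        pls = [PeakList(np.array([500.0, 600.0]), np.array([1.0, 2.0]))]
        common, aligned = hc.kde_match(pls, bandwidth=0.003)
        np.testing.assert_allclose(common.mz, [500.0, 600.0])
        np.testing.assert_allclose(aligned, [[1.0, 2.0]])

    def test_highest_count_wins_within_mode(self):
        pls = [
            PeakList(np.array([500.000]), np.array([1.0])),
            PeakList(np.array([500.000, 500.004]), np.array([1.0, 1.0])),
        ]
        common, _ = hc.kde_match(pls, bandwidth=0.003)
        assert len(common.mz) == 1 and common.mz[0] == 500.000

    def test_empty_pool_gives_empty_vector(self):
        common, aligned = hc.kde_match([PeakList(np.array([]), np.array([]))])
        assert len(common.mz) == 0 and aligned.shape == (1, 0)


class TestMatrixSteps:
    def test_mean_spectrum(self):
        assert (hc.sample_mean_spectrum(np.array([[0.0, 2.0], [2.0, 0.0]]))
                == np.array([1.0, 1.0])).all()
        reps = np.random.default_rng(0).random((5, 7))
        np.testing.assert_allclose(
            hc.sample_mean_spectrum(reps), hc.sample_mean_spectrum(reps[::-1]),
            rtol=1e-14,
        )

    def test_mfc_recovers_planted_scale(self):
        # rows are multiples of one base spectrum (pure intensity variation);
        # tripling a low row leaves the median reference untouched
        rng = np.random.default_rng(1)
        base = rng.uniform(1, 10, 30)
        scales = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        M = scales[:, None] * base
        M2 = M.copy()
        M2[0] *= 3.0
        _, f0 = hc.mfc_normalize(M)
        normed, factors = hc.mfc_normalize(M2)
        assert factors[0] / f0[0] == pytest.approx(3.0, rel=1e-12)
        np.testing.assert_allclose(normed[0], M[0] / f0[0], rtol=1e-12)

    def test_already_normalized_matrix_has_unit_factors(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(1, 10, 20)
        M = np.array([1.0, 3.0, 5.0, 7.0, 9.0])[:, None] * base
        normed, _ = hc.mfc_normalize(M)
        _, factors = hc.mfc_normalize(normed)
        np.testing.assert_allclose(factors, 1.0, atol=1e-12)

    def test_post_normalization_median_ratio_is_one(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            M = rng.uniform(0, 5, (7, 40))
            normed, _ = hc.mfc_normalize(M)
            ref = np.median(M, axis=0)
            for row in normed:
                ok = (row > 0) & (ref > 0)
                assert np.median(row[ok] / ref[ok]) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_sample_warns_and_keeps_factor_one(self):
        M = np.array([[1.0, 1.0, 0.0], [2.0, 2.0, 0.0], [0.0, 0.0, 5.0]])
        with pytest.warns(UserWarning, match="no nonzero features"):
            _, factors = hc.mfc_normalize(M)
        assert factors[2] == 1.0

    def test_log_transform(self):
        M = np.array([[0.0, np.e - 1.0, 5.0, 2.0]])
        out = hc.log_transform(M)
        assert out[0, 0] == 0.0
        assert out[0, 1] == pytest.approx(1.0)
        assert (np.argsort(out[0]) == np.argsort(M[0])).all()
        with pytest.raises(ValueError, match="non-negative"):
            hc.log_transform(np.array([[-1.0]]))


def test_detect_is_idempotent_on_apex_only_vectors():
    v = np.zeros(3000)
    v[[500, 900, 2200]] = [100.0, 250.0, 80.0]
    first = hc.detect_peaks(v, CFG)
    sparse = np.zeros_like(v)
    idx = np.searchsorted(CFG.centers(), first.mz)
    sparse[idx] = first.intensity
    second = hc.detect_peaks(sparse, CFG)
    np.testing.assert_array_equal(first.mz, second.mz)


def test_text_reader_roundtrip(tmp_path):
    p = tmp_path / "spec.txt"
    np.savetxt(p, np.column_stack([[200.0, 300.0], [5.0, 6.0]]))
    sp = read_spectrum_text(p, sample_id="s", replicate=2)
    assert sp.sample_id == "s" and sp.replicate == 2
    np.testing.assert_allclose(sp.mz, [200.0, 300.0])


def test_end_to_end_recovery_of_planted_peaks():
    """Class-distinct planted peaks survive the whole chain and remain
    class-separable after normalization and the log transform."""
    classes = {"a": [300.0, 420.0, 510.5], "b": [300.0, 380.25, 555.75]}
    spectra, truth = hc.gen_synthetic_spectra(
        classes, jitter_sigma=0.002, noise_level=1.0, scale_range=(0.5, 5.0),
        replicates=4, samples_per_class=3, mz_range=(150.0, 1000.0), seed=5,
    )
    df, log = hc.preprocess_spectra(spectra, CFG)
    planted = sorted(set(sum(truth["classes"].values(), [])))
    feats = np.array([float(c) for c in df.columns])
    assert len(feats) == len(planted) == 5
    assert np.abs(feats - planted).max() <= 0.003
    # class-distinct features separate the classes after the transform chain
    a_rows = [i for i, s in enumerate(df.index) if s.startswith("a")]
    b_rows = [i for i, s in enumerate(df.index) if s.startswith("b")]
    only_a = np.argmin(np.abs(feats - 420.0))
    assert df.values[a_rows, only_a].min() > df.values[b_rows, only_a].max()
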