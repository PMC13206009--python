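"""Reconstruction/regression metrics, wavelength map, baselines, stability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brixband import metrics

rng = np.random.default_rng(13)


def _reference_recon_metrics(x, x_hat):
    """Independent straightforward double-loop implementation."""
    c, h, w = x.shape
    abs_sum = sq_sum = 0.0
    for ci in range(c):
        for hi in range(h):
            for wi in range(w):
                d = x_hat[ci, hi, wi] - x[ci, hi, wi]
                abs_sum += abs(d)
                sq_sum += d * d
    mae = abs_sum / (c * h * w)
    mse = sq_sum / (c * h * w)
    psnr = np.inf if mse == 0 else 10 * np.log10(1.0 / mse)
    ssims = []
    for ci in range(c):
        a, b = x[ci].ravel(), x_hat[ci].ravel()
        mu_a, mu_b = a.mean(), b.mean()
        cov = ((a - mu_a) * (b - mu_b)).mean()
        ssims.append((2 * mu_a * mu_b + 1e-4) * (2 * cov + 9e-4)
                     / ((mu_a ** 2 + mu_b ** 2 + 1e-4)
                        * (a.var() + b.var() + 9e-4)))
    sccs, sams = [], []
    for hi in range(h):
        for wi in range(w):
            sa, sb = x[:, hi, wi], x_hat[:, hi, wi]
            da, db = sa - sa.mean(), sb - sb.mean()
            denom = np.sqrt((da ** 2).sum() * (db ** 2).sum())
            sccs.append((da * db).sum() / denom if denom > 0 else 0.0)
            nn_ = np.sqrt((sa ** 2).sum() * (sb ** 2).sum())
            cos = np.clip((sa * sb).sum() / nn_, -1, 1) if nn_ > 0 else 1.0
            sams.append(np.degrees(np.arccos(cos)))
    return (mae, mse, psnr, float(np.mean(ssims)), float(np.mean(sccs)),
            float(np.mean(sams)))


class TestReconMetrics:
    def test_identity_is_perfect(self):
        x = rng.uniform(0.1, 0.9, size=(3, 4, 4))
        m = metrics.recon_metrics(x, x)
        assert m.mae == 0 and m.mse == 0 and m.sam == 0
        assert m.psnr == np.inf
        assert m.ssim == pytest.approx(1.0)
        assert m.scc == pytest.approx(1.0)

    def test_constant_offset_closed_form(self):
        x = rng.uniform(0.3, 0.6, size=(3, 5, 5))
        m = metrics.recon_metrics(x, x + 0.1)
        assert m.mse == pytest.approx(0.01)
        assert m.mae == pytest.approx(0.1)
        assert m.psnr == pytest.approx(-20 * np.log10(0.1))

    def test_two_band_45_degree_angle(self):
        x = np.zeros((2, 1, 1))
        x[:, 0, 0] = [1.0, 0.0]
        xh = np.ones((2, 1, 1))
        assert metrics.recon_metrics(x, xh).sam == pytest.approx(45.0)

    def test_agrees_with_double_loop_reference_on_toys(self):
        for _ in range(5):
            x = rng.uniform(size=(3, 4, 4))
            xh = rng.uniform(size=(3, 4, 4))
            m = metrics.recon_metrics(x, xh)
            ref = _reference_recon_metrics(x, xh)
            for got, want in zip((m.mae, m.mse, m.psnr, m.ssim, m.scc,
                                  m.sam), ref):
                assert got == pytest.approx(want, abs=1e-10)

    def test_gaussian_window_mode_matches_skimage(self):
        from skimage.metrics import structural_similarity

        x = rng.uniform(size=(2, 16, 16))
        xh = np.clip(x + rng.normal(0, 0.05, x.shape), 0, 1)
        m = metrics.recon_metrics(x, xh, ssim_mode="gaussian")
        want = np.mean([structural_similarity(
            x[i], xh[i], data_range=1.0, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False) for i in range(2)])
        assert m.ssim == pytest.approx(want, abs=1e-12)

    def test_invariant_bounds_fuzz(self):
        for _ in range(100):
            x = rng.uniform(size=(3, 3, 3))
            xh = rng.uniform(size=(3, 3, 3))
            m = metrics.recon_metrics(x, xh)
            assert m.mse >= 0 and -1 <= m.scc <= 1 and m.sam >= 0
            assert -1 <= m.ssim <= 1


class TestRegMetrics:
    def test_perfect_prediction(self):
        y = np.array([8.0, 10.0, 12.0])
        m = metrics.reg_metrics(y, y)
        assert m.rmse == 0 and m.r2 == 1.0 and m.rpd == np.inf

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([8.0, 10.0, 12.0])
        m = metrics.reg_metrics(y, np.full(3, y.mean()))
        assert m.r2 == pytest.approx(0.0)

    def test_hand_arithmetic_example(self):
        m = metrics.reg_metrics(np.array([1.0, 2.0, 3.0]),
                                np.array([1.0, 2.0, 4.0]))
        assert m.r2 == pytest.approx(0.5)
        assert m.rmse == pytest.approx(np.sqrt(1 / 3))
        assert m.mae == pytest.approx(1 / 3)

    def test_rpd_times_rmse_is_label_sd(self):
        for _ in range(20):
            y = rng.normal(10, 1.4, size=30)
            yh = y + rng.normal(0, 0.5, size=30)
            m = metrics.reg_metrics(y, yh)
            assert m.rpd * m.rmse == pytest.approx(y.std(), abs=1e-9)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            metrics.reg_metrics(np.full(5, 10.0), rng.normal(size=5))


class TestWavelengthMap:
    def test_instrument_range_endpoints(self):
        assert metrics.band_to_wavelength(0, 176, (404.7, 1010.8)) \
            == pytest.approx(404.7)
        assert metrics.band_to_wavelength(175, 176, (404.7, 1010.8)) \
            == pytest.approx(1010.8)

    def test_linearity_at_midpoint(self):
        lo = metrics.band_to_wavelength(87, 176, (404.7, 1010.8))
        hi = metrics.band_to_wavelength(88, 176, (404.7, 1010.8))
        assert (lo + hi) / 2 == pytest.approx((404.7 + 1010.8) / 2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            metrics.band_to_wavelength(176, 176, (404.7, 1010.8))
        with pytest.raises(ValueError):
            metrics.band_to_wavelength(-1, 176, (404.7, 1010.8))


class TestBaselines:
    def test_random_is_seeded_and_distinct(self):
        a = metrics.baseline_select("random", None, 10, seed=3, n_bands=32)
        b = metrics.baseline_select("random", None, 10, seed=3, n_bands=32)
        np.testing.assert_array_equal(a, b)
        assert len(set(a.tolist())) == 10

    def test_k_equals_c_returns_all(self):
        data = rng.uniform(size=(4, 6, 3, 3))
        for method in ("random", "variance"):
            out = metrics.baseline_select(method, data, 6, seed=0,
                                          n_bands=6)
            np.testing.assert_array_equal(out, np.arange(6))

    def test_variance_ranks_inflated_bands_first(self):
        data = rng.uniform(0.4, 0.6, size=(12, 8, 4, 4))
        hot = [1, 4, 6]
        data[:, hot] += rng.normal(0, 0.5, size=(12, 3, 4, 4))
        out = metrics.baseline_select("variance", data, 6, seed=0)
        assert set(hot) <= set(out.tolist())

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            metrics.baseline_select("random", None, 40, n_bands=32)


class TestStability:
    def test_jaccard_identities(self):
        assert metrics.jaccard([1, 2, 3], [1, 2, 3]) == 1.0
        assert metrics.jaccard([1, 2], [3, 4]) == 0.0
        assert metrics.jaccard([1, 2, 3], [2, 3, 4]) == 0.5

    def test_report_shapes_and_normalization(self):
        subsets = [np.array([0, 1, 2]), np.array([1, 2, 3]),
                   np.array([1, 2, 3])]
        final = np.array([1, 2, 3])
        freqs = {"train": np.array([4.0, 8.0, 6.0, 2.0]),
                 "val": np.array([1.0, 2.0, 2.0, 0.0])}
        rep = metrics.stability_report(subsets, final, freqs)
        np.testing.assert_allclose(rep.jaccard_to_previous, [0.5, 1.0])
        np.testing.assert_allclose(rep.overlap_with_final, [2 / 3, 1.0, 1.0])
        for split_name in freqs:
            assert rep.normalized_frequencies[split_name].max() == 1.0
        assert rep.top15["train"][0] == 1


class TestBandEntropy:
    def test_constant_band_has_zero_entropy(self):
        cubes = np.full((2, 3, 4, 4), 0.5)
        np.testing.assert_allclose(metrics.band_entropy(cubes, 16), 0.0)

    def test_uniform_histogram_hits_log2_bins(self):
        # 16 voxels placed exactly one per bin -> 4 bits
        vals = (np.arange(16) + 0.5) / 16
        cube = vals.reshape(1, 1, 4, 4)
        ent = metrics.band_entropy(cube, 16)
        assert ent[0] == pytest.approx(4.0)

    def test_invariant_to_histogram_mass_permutation(self):
        vals = rng.uniform(size=(1, 1, 8, 8))
        ent1 = metrics.band_entropy(vals, 16)
        # monotone relabeling that permutes bin contents: x -> 1 - x
        ent2 = metrics.band_entropy(1.0 - vals, 16)
        assert ent1[0] == pytest.approx(ent2[0], abs=1e-12)


@settings(derandomize=True, max_examples=30)
@given(st.integers(2, 300), st.integers(2, 300))
def test_wavelength_map_is_affine_for_any_band_count(n_bands, idx_seed):
    idx = idx_seed % n_bands
    wl = metrics.band_to_wavelength(idx, n_bands, (400.0, 1000.0))
    assert wl == pytest.approx(400.0 + idx * 600.0 / (n_bands - 1))
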