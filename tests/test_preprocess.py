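"""Normalization, resampling, discretisation and the filter bank."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from discradiomics import (
    PreprocessConfig,
    build_filter_bank,
    discretise,
    log_filter,
    normalize_image,
    resample2d,
    wavelet_bank,
)


class TestNormalize:
    def test_constant_image_warns_and_zeros(self):
        img = np.full((8, 8), 7.0)
        with pytest.warns(UserWarning):
            out = normalize_image(img, np.ones((8, 8), bool))
        assert np.all(out == 0)

    def test_one_sigma_pixel(self):
        # half 80s and half 120s: mu = 100, sigma = 20
        img = np.concatenate([np.full(32, 80.0), np.full(32, 120.0)]).reshape(8, 8)
        out = normalize_image(img, np.ones((8, 8), bool), scale=100.0)
        assert out[img == 120][0] == pytest.approx(100.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            np.float64,
            (6, 6),
            elements=st.floats(-100, 100, allow_nan=False),
        )
    )
    def test_idempotent(self, img):
        if img.std() == 0:
            return
        once = normalize_image(img, None, 100.0)
        twice = normalize_image(once, None, 100.0)
        np.testing.assert_allclose(twice, once, atol=1e-8)


class TestResample:
    def test_factor_one_identity(self):
        img = np.arange(16.0).reshape(4, 4)
        mask = img > 5
        out_i, out_m = resample2d(img, mask, 1)
        np.testing.assert_array_equal(out_i, img)
        np.testing.assert_array_equal(out_m, mask)

    def test_mask_nearest_neighbour_oracle(self):
        mask = np.zeros((10, 10), bool)
        mask[3:7, 3:7] = True
        _, up = resample2d(np.zeros((10, 10)), mask, 2)
        assert up.shape == (20, 20)
        expected = np.kron(mask, np.ones((2, 2), bool))
        np.testing.assert_array_equal(up, expected)
        assert up.sum() == 4 * mask.sum()

    def test_mask_stays_binary(self):
        rng = np.random.default_rng(0)
        mask = rng.random((9, 9)) > 0.5
        _, up = resample2d(rng.random((9, 9)), mask, 3)
        assert up.dtype == bool

    def test_bad_factor(self):
        with pytest.raises(ValueError):
            resample2d(np.zeros((4, 4)), np.ones((4, 4), bool), 0)


class TestDiscretise:
    def test_anchor_rule_hand_computed(self):
        img = np.array([[0.0, 15.9], [16.0, 32.0]])
        bins, n = discretise(img, np.ones((2, 2), bool), 16.0)
        np.testing.assert_array_equal(bins, [[1, 1], [2, 3]])
        assert n == 3

    def test_negative_values_anchor(self):
        img = np.array([[-17.0, -1.0], [0.0, 15.0]])
        bins, n = discretise(img, np.ones((2, 2), bool), 16.0)
        # anchor floor(-17/16)*16 = -32
        np.testing.assert_array_equal(bins, [[1, 2], [3, 3]])

    def test_constant_region_single_level(self):
        bins, n = discretise(np.full((3, 3), 5.0), np.ones((3, 3), bool), 16.0)
        assert n == 1
        assert set(bins.ravel()) == {1}

    def test_level_count_bounded(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 250, (12, 12))
        mask = rng.random((12, 12)) > 0.3
        bins, n = discretise(img, mask, 16.0)
        rng_in = np.ptp(img[mask])
        assert n <= np.ceil(rng_in / 16.0) + 1

    def test_bad_width(self):
        with pytest.raises(ValueError):
            discretise(np.zeros((2, 2)), np.ones((2, 2), bool), 0)


class TestLoG:
    def test_flat_image_zero_response(self):
        out = log_filter(np.full((32, 32), 9.0), 2.0, 1.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_impulse_matches_analytic_kernel(self):
        n = 129
        img = np.zeros((n, n))
        img[n // 2, n // 2] = 1.0
        sigma = 6.0
        out = log_filter(img, sigma, 1.0)
        yy, xx = np.mgrid[:n, :n] - n // 2
        g = np.exp(-(xx**2 + yy**2) / (2 * sigma**2)) / (2 * np.pi * sigma**2)
        analytic = g * ((xx**2 + yy**2) - 2 * sigma**2) / sigma**4
        np.testing.assert_allclose(out, analytic, atol=1e-6)

    def test_zero_mean_response(self):
        rng = np.random.default_rng(0)
        out = log_filter(rng.random((64, 64)), 2.0, 1.0)
        assert abs(out.mean()) < 1e-3

    def test_subpixel_sigma_warns(self):
        with pytest.warns(UserWarning):
            log_filter(np.zeros((16, 16)), 0.5, 1.0)


class TestWavelet:
    def test_constant_image_no_detail(self):
        bank = wavelet_bank(np.full((16, 16), 3.0))
        for sub in ("LH", "HL", "HH"):
            np.testing.assert_allclose(bank[sub], 0.0, atol=1e-12)

    def test_parseval_energy(self):
        import pywt

        rng = np.random.default_rng(2)
        img = rng.normal(size=(16, 16))
        ll, (lh, hl, hh) = pywt.dwt2(img, "haar")
        total = sum(np.sum(b**2) for b in (ll, lh, hl, hh))
        assert total == pytest.approx(np.sum(img**2), rel=1e-10)

    def test_output_shapes_match_input(self):
        img = np.random.default_rng(3).normal(size=(15, 17))
        bank = wavelet_bank(img)
        assert all(b.shape == img.shape for b in bank.values())

    def test_unknown_basis_rejected(self):
        with pytest.raises(ValueError):
            wavelet_bank(np.zeros((8, 8)), basis="nosuchwavelet")


class TestFilterBank:
    def test_default_eight_sets(self):
        img = np.random.default_rng(0).normal(size=(32, 32))
        sets = build_filter_bank(img, np.ones((32, 32), bool), PreprocessConfig(), 0.5)
        assert len(sets) == 8
        assert len(set(sets)) == 8
        assert all(a.shape == img.shape for a in sets.values())

    def test_no_log_sigmas_gives_five_sets(self):
        img = np.random.default_rng(0).normal(size=(16, 16))
        cfg = PreprocessConfig(log_sigmas_mm=())
        sets = build_filter_bank(img, np.ones((16, 16), bool), cfg, 1.0)
        assert len(sets) == 5

    def test_count_identity(self):
        cfg = PreprocessConfig()
        assert cfg.n_image_sets == 1 + len(cfg.log_sigmas_mm) + 4
        assert 91 * cfg.n_image_sets + 9 == 737

    def test_yaml_round_trip(self):
        import yaml

        cfg = PreprocessConfig(bin_width=8, log_sigmas_mm=(2.0,))
        d = yaml.safe_load(yaml.safe_dump(cfg.to_dict()))
        assert PreprocessConfig.from_dict(d) == cfg
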