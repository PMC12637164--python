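"""Perturbation operator contracts: morphology, transforms, noise, suite."""

import numpy as np
import pytest
import yaml

from discradiomics.perturb import (
    PerturbationSpec,
    add_noise,
    apply_perturbation,
    build_perturbation_suite,
    dilate,
    draw_shift,
    erode,
    randomize_contour,
    rotate,
    translate,
)


def _disk(radius, size):
    yy, xx = np.mgrid[:size, :size]
    c = size / 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


class TestMorphology:
    def test_single_pixel_dilation_enumeration(self):
        m = np.zeros((6, 6), bool)
        m[2, 2] = True
        out = dilate(m)
        want = np.zeros((6, 6), bool)
        want[2:4, 2:4] = True  # top-left anchored 2x2 footprint
        np.testing.assert_array_equal(out, want)

    def test_block_erosion_enumeration(self):
        m = np.zeros((6, 6), bool)
        m[1:4, 1:4] = True
        out = erode(m)
        want = np.zeros((6, 6), bool)
        want[1:3, 1:3] = True  # survives where the anchored 2x2 fits
        np.testing.assert_array_equal(out, want)

    def test_extensivity_and_duality(self, disc_g2):
        m = disc_g2.slices[0].disc_mask
        d = dilate(m)
        e = erode(m)
        assert np.all(d[m])  # superset
        assert not np.any(e & ~m)  # subset
        assert d.sum() >= m.sum() >= e.sum()
        # opening is anti-extensive w.r.t. dilation; closing is extensive
        assert not np.any(dilate(erode(m)) & ~d)
        assert np.all(erode(dilate(m))[m])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            dilate(np.zeros((4, 4), bool))
        with pytest.raises(ValueError):
            erode(np.zeros((4, 4), bool))


class TestContourRandomization:
    def test_p_one_equals_dilate(self, disc_g2):
        m = disc_g2.slices[0].disc_mask
        out = randomize_contour(m, np.random.default_rng(0), p_dilate=1.0)
        np.testing.assert_array_equal(out, dilate(m))

    def test_jaccard_floor(self):
        rng = np.random.default_rng(0)
        m = _disk(12, 40)  # ~450 px
        for _ in range(20):
            out = randomize_contour(m, rng)
            j = (out & m).sum() / (out | m).sum()
            assert j > 0.6

    def test_deterministic_under_seed(self, disc_g2):
        m = disc_g2.slices[0].disc_mask
        a = randomize_contour(m, np.random.default_rng(9))
        b = randomize_contour(m, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)


class TestTranslate:
    def test_inverse_shifts_identity_on_interior(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (30, 30))
        mask = _disk(6, 30)
        i1, m1 = translate(img, mask, shift=(3, -2))
        i2, m2 = translate(i1, m1, shift=(-3, 2))
        np.testing.assert_allclose(i2[4:-4, 4:-4], img[4:-4, 4:-4])
        np.testing.assert_array_equal(m2, mask)

    def test_area_conserved_in_frame(self):
        mask = _disk(5, 40)
        rng = np.random.default_rng(1)
        for _ in range(10):
            _, m = translate(np.zeros((40, 40)), mask, rng)
            assert m.sum() == mask.sum()

    def test_drawn_magnitudes_support(self):
        rng = np.random.default_rng(2)
        mags = np.abs([draw_shift(rng) for _ in range(10_000)])
        assert mags.min() == 1 and mags.max() == 10
        assert set(np.unique(mags)) == set(range(1, 11))


class TestRotate:
    def test_full_turn_identity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (40, 40))
        mask = _disk(8, 40)
        out_i, out_m = rotate(img, mask, angle=360.0)
        np.testing.assert_allclose(out_i, img, atol=1e-8)
        np.testing.assert_array_equal(out_m, mask)

    def test_disk_area_conserved_within_5pct(self):
        mask = _disk(13, 64)  # ~500 px
        rng = np.random.default_rng(3)
        for _ in range(100):
            _, m = rotate(np.zeros((64, 64)), mask, rng)
            assert abs(m.sum() - mask.sum()) / mask.sum() < 0.05
            assert m.dtype == bool


class TestNoise:
    def test_clipping_and_moments(self):
        rng = np.random.default_rng(0)
        img = np.full((256, 256), 128.0)
        out = add_noise(img, rng)
        assert out.min() >= 0 and out.max() <= 255
        diff = out - img
        assert abs(diff.mean()) < 0.5
        assert abs(diff.std() - 8.0) < 0.5


class TestSuite:
    def test_default_six_specs_with_targets(self):
        suite = build_perturbation_suite()
        assert len(suite) == 6
        targets = {s.kind: s.target for s in suite}
        assert targets["dilation"] == "mask"
        assert targets["erosion"] == "mask"
        assert targets["contour_randomization"] == "mask"
        assert targets["translation"] == "image+mask"
        assert targets["rotation"] == "image+mask"
        assert targets["gaussian_noise"] == "image"

    def test_replicates_grow_suite(self):
        assert len(build_perturbation_suite(replicates=2)) == 10

    def test_yaml_round_trip(self):
        suite = build_perturbation_suite(replicates=2, seed=5)
        dumped = yaml.safe_dump([s.to_dict() for s in suite])
        loaded = [PerturbationSpec.from_dict(d) for d in yaml.safe_load(dumped)]
        assert loaded == suite

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            PerturbationSpec("shear")

    def test_apply_flags_emptied_mask(self):
        # a mask hugging the frame corner translated far away can empty out
        mask = np.zeros((12, 12), bool)
        mask[:2, :2] = True
        img = np.zeros((12, 12))
        spec = PerturbationSpec("translation", seed=1)
        emptied = False
        for extra in range(50):
            _, m, ok = apply_perturbation(spec, img, mask, extra_seed=extra)
            if not ok:
                emptied = True
                assert not m.any()
        assert emptied

    def test_suite_reproducible(self, disc_g2):
        sl = disc_g2.slices[0]
        for spec in build_perturbation_suite(seed=4):
            i1, m1, _ = apply_perturbation(spec, sl.image, sl.disc_mask, extra_seed=3)
            i2, m2, _ = apply_perturbation(spec, sl.image, sl.disc_mask, extra_seed=3)
            np.testing.assert_array_equal(i1, i2)
            np.testing.assert_array_equal(m1, m2)


class TestPerturbedPairWriter:
    def test_filename_suffix_convention(self, tmp_path, disc_g2):
        from discradiomics.io import write_perturbed_pair

        sl = disc_g2.slices[0]
        spec = PerturbationSpec("dilation", seed=4)
        img_p, mask_p = write_perturbed_pair(
            tmp_path, "S0001_L4-L5_s0", spec, sl.image, sl.disc_mask
        )
        assert img_p.name == "S0001_L4-L5_s0_pert-dilation-4.png"
        assert mask_p.exists()
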