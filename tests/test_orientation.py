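"""Hough orientation detection and circular statistics."""

import dataclasses
import math

import numpy as np
import pytest

import shgquant as sq
from shgquant.orientation import (analyze_angles, angle_histogram, binarize,
                                  circular_sd_deg, detect_fiber_directions,
                                  distribution_width, hough_lines,
                                  relative_angles, wrap_relative)


def test_wrap_relative_range_and_values():
    rel = wrap_relative(np.array([10.0, 100.0, 179.0]), 20.0)
    np.testing.assert_allclose(rel, [-10.0, 80.0, -21.0])
    assert wrap_relative(np.array([110.0]), 20.0)[0] == 90.0  # boundary -> +90
    a = np.linspace(0, 179.9, 50)
    r = wrap_relative(a, 77.0)
    assert ((r > -90.0) & (r <= 90.0)).all()


def test_relative_angles_excludes_reference(rng):
    dirs = np.array([10.0, 50.0, 120.0])
    idx, ref, rel = relative_angles(dirs, seed=3)
    assert rel.size == 2
    assert ref == dirs[idx]
    idx2, ref2, _ = relative_angles(dirs, reference_index=1)
    assert (idx2, ref2) == (1, 50.0)
    with pytest.raises(ValueError):
        relative_angles(np.array([]))


def test_angle_histogram_probability():
    edges, probs = angle_histogram(np.array([-10.0, 0.0, 1.0, 45.0]), 5.0)
    assert probs.sum() == pytest.approx(1.0)
    assert edges[0] == -90.0 and edges[-1] == 90.0
    assert len(probs) == 36


def test_angle_histogram_bad_width_warns():
    with pytest.warns(UserWarning, match="does not divide 180"):
        angle_histogram(np.array([0.0, 1.0]), bin_width=7.0)


def test_circular_sd_recovers_wrapped_normal():
    rng = np.random.default_rng(0)
    for sigma in (3.0, 15.0, 25.0):
        a = np.mod(rng.normal(90.0, sigma, 20000), 180.0)
        assert circular_sd_deg(a) == pytest.approx(sigma, rel=0.05)


def test_circular_sd_shift_invariant():
    rng = np.random.default_rng(1)
    a = np.mod(rng.normal(10.0, 12.0, 5000), 180.0)  # straddles the wrap
    b = np.mod(a + 63.0, 180.0)
    assert circular_sd_deg(a) == pytest.approx(circular_sd_deg(b), abs=1e-9)
    assert circular_sd_deg(np.full(10, 42.0)) == 0.0


def test_distribution_width_methods():
    rng = np.random.default_rng(2)
    rel = rng.normal(0.0, 10.0, 5000)
    sd = distribution_width(rel, method="circular_sd")
    fwhm = distribution_width(rel, method="fwhm")
    assert sd == pytest.approx(10.0, rel=0.1)
    # FWHM of a Gaussian is 2.355 sigma; histogram smoothing loosens this
    assert 15.0 < fwhm < 35.0
    with pytest.raises(ValueError, match="unknown width method"):
        distribution_width(rel, method="iqr")


def test_binarize_strict_and_default():
    img = np.full((20, 20), 2)
    img[0, 0] = 5
    # noise threshold ~0.20075: every pixel above it
    assert binarize(img).all()
    mask = binarize(img, threshold=2.0)  # strict: the 2s are excluded
    assert mask.sum() == 1


def test_hough_lines_synthetic_mask():
    mask = np.zeros((60, 60), dtype=bool)
    rr = np.arange(10, 50)
    mask[30, rr] = True  # horizontal line -> direction 0
    peaks = hough_lines(mask, min_votes=20)
    assert len(peaks) >= 1
    assert min(abs(wrap_relative(np.array([p.direction]), 0.0)[0])
               for p in peaks) <= 1.0
    assert hough_lines(np.zeros((10, 10), dtype=bool)) == []


def test_detect_single_fiber_angle(single_fiber_config):
    cfg = dataclasses.replace(single_fiber_config, mean_orientation=37.0,
                              angular_sigma=0.0)
    img = sq.generate_image(cfg, True, seed=21)
    dirs = detect_fiber_directions(img)
    assert dirs.size >= 1
    err = np.abs(wrap_relative(dirs, img.fiber_angles[0]))
    assert err.min() <= 1.0


def test_detect_background_empty(background_image):
    assert detect_fiber_directions(background_image).size == 0


def test_analyze_angles_group_mode():
    rng = np.random.default_rng(3)
    per_image = [np.mod(rng.normal(90, 8, 12), 180.0) for _ in range(10)]
    aset = analyze_angles(per_image, seed=0, reference_mode="group")
    assert aset.relative_angles.size == 120 - 1  # reference excluded
    assert aset.probabilities.sum() == pytest.approx(1.0)
    assert aset.widths["circular_sd"] == pytest.approx(8.0, rel=0.25)
    assert aset.width == aset.widths["circular_sd"]


def test_analyze_angles_image_mode():
    rng = np.random.default_rng(4)
    per_image = [np.mod(rng.normal(90, 8, 12), 180.0) for _ in range(10)]
    aset = analyze_angles(per_image, seed=0, reference_mode="image")
    assert aset.relative_angles.size == 120 - 10  # one reference per image
    with pytest.raises(ValueError, match="unknown reference_mode"):
        analyze_angles(per_image, reference_mode="global")


def test_analyze_angles_requires_fibers():
    with pytest.raises(ValueError, match="no fibers"):
        analyze_angles([np.array([])])
    with pytest.raises(ValueError, match="at least two"):
        analyze_angles([np.array([45.0])])


def test_group_width_reference_invariant():
    rng = np.random.default_rng(5)
    per_image = [np.mod(rng.normal(60, 12, 10), 180.0) for _ in range(8)]
    widths = {analyze_angles(per_image, seed=s).widths["circular_sd"]
              for s in range(5)}
    assert len({round(w, 9) for w in widths}) == 1
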