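"""Window/image statistics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from shgquant.features import (image_features, intensity_distribution,
                               noise_threshold, sliding_window_features,
                               window_statistics)


def loop_window_stats(window, threshold, factor):
    """Naive reference implementation of the seven statistics."""
    flat = [float(v) for v in np.asarray(window).ravel()]
    n = len(flat)
    mu = sum(flat) / n
    var = sum((v - mu) ** 2 for v in flat) / n
    std = var ** 0.5
    if std == 0:
        skew = kurt = 0.0
    else:
        skew = sum((v - mu) ** 3 for v in flat) / n / std**3
        kurt = sum((v - mu) ** 4 for v in flat) / n / std**4
    counts = {}
    for v in flat:
        counts[int(v)] = counts.get(int(v), 0) + 1
    best = max(counts.values())
    mode = min(v for v, c in counts.items() if c == best)
    total = int(round(sum(flat)))
    frac = sum(1 for v in flat if v > factor * threshold) / n
    return mu, std, skew, kurt, mode, total, frac


def test_noise_threshold_constant_image():
    img = np.full((32, 32), 7)
    assert noise_threshold(img) == pytest.approx(0.7, abs=1e-12)
    # unnormalized convention scales by the pixel count
    assert noise_threshold(img, normalized=False) == \
        pytest.approx(0.7 * 32 * 32, rel=1e-12)


@settings(max_examples=50, deadline=None)
@given(arrays(np.int64, (12, 17), elements=st.integers(0, 500)))
def test_noise_threshold_is_mean_over_ten(counts):
    # for non-negative images the DC term dominates the DFT amplitude
    assert noise_threshold(counts) == pytest.approx(counts.mean() / 10.0,
                                                    rel=1e-12, abs=1e-12)


def test_window_statistics_matches_scipy(rng):
    w = rng.integers(0, 40, size=(20, 20))
    thr = 1.3
    wf = window_statistics(w, thr, factor=0.15)
    flat = w.ravel().astype(float)
    assert wf.mean == pytest.approx(flat.mean())
    assert wf.std == pytest.approx(flat.std())  # population SD
    assert wf.skewness == pytest.approx(stats.skew(flat, bias=True))
    assert wf.kurtosis == pytest.approx(stats.kurtosis(flat, bias=True,
                                                       fisher=False))
    assert wf.sum == flat.sum()
    assert wf.frac_above == pytest.approx(np.mean(flat > 0.15 * thr))


def test_degenerate_window_conventions():
    wf = window_statistics(np.full((5, 5), 4), threshold=10.0, factor=1.0)
    assert wf.std == 0.0 and wf.skewness == 0.0 and wf.kurtosis == 0.0
    assert wf.mode == 4 and wf.sum == 100
    assert wf.frac_above == 0.0  # 4 > 10 is false (strict comparison)


def test_mode_tie_breaks_to_smallest():
    w = np.array([[3, 3, 8], [8, 1, 2], [5, 6, 7]])
    assert window_statistics(w, 1.0).mode == 3


def test_frac_above_strict():
    w = np.full((4, 4), 2)
    w[0, 0] = 3
    # threshold*factor == 2 exactly: only the single 3 counts
    assert window_statistics(w, 2.0, factor=1.0).frac_above == \
        pytest.approx(1 / 16)


def test_window_too_small_rejected():
    with pytest.raises(ValueError, match="2x2"):
        window_statistics(np.array([[1, 2, 3]]), 1.0)


def test_sliding_window_count_and_order(rng):
    img = rng.integers(0, 30, size=(26, 24))
    feats = sliding_window_features(img, window_size=20, stride=1)
    assert len(feats) == 7 * 5
    assert (feats[0].row, feats[0].col) == (0, 0)
    assert (feats[-1].row, feats[-1].col) == (6, 4)
    strided = sliding_window_features(img, window_size=20, stride=3)
    assert len(strided) == 3 * 2


def test_sliding_windows_match_loop_oracle(rng):
    img = rng.integers(0, 25, size=(24, 23))
    thr = noise_threshold(img)
    for wf in sliding_window_features(img, window_size=20, stride=2):
        win = img[wf.row:wf.row + 20, wf.col:wf.col + 20]
        mu, std, skew, kurt, mode, total, frac = \
            loop_window_stats(win, thr, 0.15)
        assert wf.mean == pytest.approx(mu)
        assert wf.std == pytest.approx(std)
        assert wf.skewness == pytest.approx(skew)
        assert wf.kurtosis == pytest.approx(kurt)
        assert wf.mode == mode
        assert wf.sum == total
        assert wf.frac_above == pytest.approx(frac)


def test_image_smaller_than_window_rejected(rng):
    with pytest.raises(ValueError, match="smaller than window"):
        sliding_window_features(rng.integers(0, 5, (10, 10)), window_size=20)


def test_image_features_constant_image():
    fv = image_features(np.full((20, 20), 5))
    assert fv.mean_over_std is None
    assert fv.mode == 5 and fv.sum == 2000
    assert fv.frac_above == 1.0  # 5 > 0.5 for every pixel


def test_intensity_distribution_sums_to_one(rng):
    pix = rng.integers(0, 8, size=200)
    dist = intensity_distribution(pix)
    assert sum(dist.values()) == pytest.approx(1.0)
    assert dist[int(pix[0])] > 0
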