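"""Statistical feature extraction from photon-count images.

Per sliding window (20x20, stride 1 by default) the seven statistics are:
mean, standard deviation, skewness, kurtosis (population moments;
kurtosis non-excess), statistical mode (most frequent integer count, ties
broken toward the smallest value), total intensity sum, and the fraction
of pixels whose intensity strictly exceeds ``factor`` times the image's
noise threshold.

The noise threshold is one-tenth of the maximum amplitude of the image's
2-D discrete Fourier transform. Under the normalized convention used here
(magnitudes divided by the pixel count) the maximum for a non-negative
image is the zero-frequency component, so the threshold equals the image
mean divided by ten.

Two threshold factors appear downstream: 0.15 for window-level feature
extraction and 1.0 for the image-level features fed to clustering and
classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imgio import IntensityImage

#: Default comparison factor for window-level features (15% of threshold).
WINDOW_FACTOR = 0.15
#: Default comparison factor for image-level features (the full threshold).
IMAGE_FACTOR = 1.0

IMAGE_FEATURE_NAMES = ("mean", "std", "mean_over_std", "mode", "sum", "frac_above")
#: The four image-level features used for clustering.
CLUSTER_FEATURE_NAMES = ("mean", "std", "mode", "frac_above")


@dataclass(frozen=True)
class WindowFeatures:
    """The seven window statistics plus the window's top-left position."""

    row: int
    col: int
    mean: float
    std: float
    skewness: float
    kurtosis: float
    mode: int
    sum: int
    frac_above: float


@dataclass(frozen=True)
class ImageFeatureVector:
    """Whole-image statistics; ``mean_over_std`` is None when std == 0."""

    mean: float
    std: float
    mean_over_std: float | None
    mode: int
    sum: int
    frac_above: float


def _as_counts(image: IntensityImage | np.ndarray) -> np.ndarray:
    if isinstance(image, IntensityImage):
        return image.counts
    return np.asarray(image)


def noise_threshold(image: IntensityImage | np.ndarray,
                    normalized: bool = True) -> float:
    """One-tenth of the maximum DFT amplitude of the image.

    With ``normalized=True`` (default) magnitudes are divided by the pixel
    count, so for a non-negative image the threshold equals mean/10; the
    unnormalized variant returns max|FFT|/10 on the raw scale.
    """
    counts = _as_counts(image).astype(float)
    if counts.size == 0:
        raise ValueError("image must be non-empty")
    amp = np.abs(np.fft.fft2(counts)).max()
    if normalized:
        amp /= counts.size
    return float(amp / 10.0)


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """Population mean/std/skewness/kurtosis; skew = kurt = 0 when std = 0."""
    mu = float(x.mean())
    centered = x - mu
    var = float(np.mean(centered**2))
    std = float(np.sqrt(var))
    if std == 0.0:
        return mu, 0.0, 0.0, 0.0
    skew = float(np.mean(centered**3)) / std**3
    kurt = float(np.mean(centered**4)) / std**4
    return mu, std, skew, kurt


def _mode(x: np.ndarray) -> int:
    """Most frequent integer value; ties broken toward the smallest value."""
    flat = x.ravel().astype(np.int64)
    # bincount's argmax returns the first (smallest) index among ties
    return int(np.argmax(np.bincount(flat)))


def window_statistics(window: np.ndarray, threshold: float,
                      factor: float = WINDOW_FACTOR,
                      row: int = 0, col: int = 0) -> WindowFeatures:
    """Compute the seven statistics of one window against a shared threshold."""
    window = np.asarray(window)
    if window.ndim != 2 or window.shape[0] < 2 or window.shape[1] < 2:
        raise ValueError("window must be at least 2x2")
    flat = window.ravel().astype(float)
    mu, std, skew, kurt = _moments(flat)
    total = int(round(flat.sum()))
    frac = float(np.mean(flat > factor * threshold))
    return WindowFeatures(row=row, col=col, mean=mu, std=std, skewness=skew,
                          kurtosis=kurt, mode=_mode(window), sum=total,
                          frac_above=frac)


def sliding_window_features(image: IntensityImage | np.ndarray,
                            window_size: int = 20, stride: int = 1,
                            factor: float = WINDOW_FACTOR,
                            ) -> list[WindowFeatures]:
    """All window statistics of an image, windows in row-major order.

    The noise threshold is computed once per image and shared by all its
    windows. Produces ((H-w)//s + 1) x ((W-w)//s + 1) windows.
    """
    counts = _as_counts(image)
    h, w = counts.shape
    if h < window_size or w < window_size:
        raise ValueError(f"image {h}x{w} smaller than window {window_size}")
    thr = noise_threshold(counts)
    cmp_val = factor * thr
    windows = np.lib.stride_tricks.sliding_window_view(
        counts, (window_size, window_size))[::stride, ::stride]
    nr, nc = windows.shape[:2]
    flat = windows.reshape(nr, nc, -1).astype(float)
    area = flat.shape[-1]
    mu = flat.mean(axis=-1)
    centered = flat - mu[..., None]
    var = np.mean(centered**2, axis=-1)
    std = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(std > 0, np.mean(centered**3, axis=-1) / std**3, 0.0)
        kurt = np.where(std > 0, np.mean(centered**4, axis=-1) / std**4, 0.0)
    totals = flat.sum(axis=-1)
    fracs = np.mean(flat > cmp_val, axis=-1)

    out: list[WindowFeatures] = []
    for i in range(nr):
        for j in range(nc):
            out.append(WindowFeatures(
                row=i * stride, col=j * stride,
                mean=float(mu[i, j]), std=float(std[i, j]),
                skewness=float(skew[i, j]), kurtosis=float(kurt[i, j]),
                mode=_mode(windows[i, j]), sum=int(round(totals[i, j])),
                frac_above=float(fracs[i, j]),
            ))
    assert len(out) == ((h - window_size) // stride + 1) * \
        ((w - window_size) // stride + 1)
    assert area == window_size * window_size
    return out


def image_features(image: IntensityImage | np.ndarray,
                   factor: float = IMAGE_FACTOR) -> ImageFeatureVector:
    """Whole-image feature vector (same conventions as window_statistics)."""
    counts = _as_counts(image)
    if counts.size == 0:
        raise ValueError("image must be non-empty")
    thr = noise_threshold(counts)
    wf = window_statistics(counts, thr, factor=factor)
    ratio = wf.mean / wf.std if wf.std > 0 else None
    return ImageFeatureVector(mean=wf.mean, std=wf.std, mean_over_std=ratio,
                              mode=wf.mode, sum=wf.sum,
                              frac_above=wf.frac_above)


def intensity_distribution(pixels: np.ndarray) -> dict[int, float]:
    """Empirical probability distribution over observed intensity values."""
    flat = np.asarray(pixels).ravel()
    if flat.size == 0:
        raise ValueError("pixel vector must be non-empty")
    values, counts = np.unique(flat, return_counts=True)
    n = flat.size
    return {int(v): float(c) / n for v, c in zip(values, counts)}


def window_feature_table(images: list[IntensityImage], window_size: int = 20,
                         stride: int = 1, factor: float = WINDOW_FACTOR,
                         ) -> pd.DataFrame:
    """Window features for many images as one table.

    Adds the mean-to-std ratio column (``mean_over_std``; NaN where the
    window is constant) alongside the seven raw statistics.
    """
    records = []
    for img in images:
        for wf in sliding_window_features(img, window_size, stride, factor):
            records.append({
                "image_id": img.image_id, "group": img.group,
                "animal": img.animal, "row": wf.row, "col": wf.col,
                "mean": wf.mean, "std": wf.std, "skewness": wf.skewness,
                "kurtosis": wf.kurtosis, "mode": wf.mode, "sum": wf.sum,
                "frac_above": wf.frac_above,
                "mean_over_std": wf.mean / wf.std if wf.std > 0 else np.nan,
            })
    return pd.DataFrame(records)


def image_feature_table(images: list[IntensityImage],
                        factor: float = IMAGE_FACTOR) -> pd.DataFrame:
    """Image-level feature vectors for many images as one table."""
    records = []
    for img in images:
        fv = image_features(img, factor=factor)
        records.append({
            "image_id": img.image_id, "group": img.group, "animal": img.animal,
            "mean": fv.mean, "std": fv.std,
            "mean_over_std": fv.mean_over_std if fv.mean_over_std is not None
            else np.nan,
            "mode": fv.mode, "sum": fv.sum, "frac_above": fv.frac_above,
        })
    return pd.DataFrame(records)
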