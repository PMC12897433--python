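"""Collagen fiber orientation analysis via the Hough transform.

Fiber-positive images are binarized at the noise threshold, straight-line
candidates are detected with a standard (rho, theta) Hough accumulator,
and the detected line directions are analyzed on the period-180 degree
orientation circle: one fiber serves as the random reference, the other
fibers' orientations are expressed relative to it in (-90, 90], binned
into an angular probability histogram, and summarized by a distribution
width.

Conventions
-----------
* Fiber/line *direction* angles live in [0, 180), measured
  counter-clockwise from the +x (column) axis in the (x=col, y=row)
  frame: a horizontal line has direction 0, a vertical one 90.
* The Hough *normal* angle theta is the direction of the line's normal;
  direction = (theta + 90) mod 180.
* The default width statistic is the period-180 circular standard
  deviation (invariant to the reference choice); a full-width at half
  maximum of the smoothed histogram is available as the alternative
  reading of "distribution width".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import math

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects, skeletonize
from skimage.transform import hough_line, hough_line_peaks

from .features import noise_threshold
from .imgio import IntensityImage

#: Default minimum accumulator votes: half the default shortest fiber (30 px).
DEFAULT_MIN_VOTES = 15
DEFAULT_MAX_LINES = 25


@dataclass(frozen=True)
class HoughPeak:
    """One detected line: normal form rho/theta plus the line direction."""

    rho: float
    theta: float        # normal angle, degrees in [-90, 90)
    direction: float    # line direction, degrees in [0, 180)
    votes: int


@dataclass
class FiberAngleSet:
    """Detected fiber directions and their relative-angle summary."""

    directions: np.ndarray            # degrees in [0, 180)
    reference_angle: float
    relative_angles: np.ndarray       # degrees in (-90, 90], reference excluded
    bin_edges: np.ndarray
    probabilities: np.ndarray
    width: float
    width_method: str
    seed: int | None = None
    widths: dict[str, float] = field(default_factory=dict)


def binarize(image: IntensityImage | np.ndarray,
             threshold: float | None = None) -> np.ndarray:
    """Mask of pixels strictly above the threshold (default: noise threshold)."""
    counts = image.counts if isinstance(image, IntensityImage) else \
        np.asarray(image)
    if counts.size == 0:
        raise ValueError("image must be non-empty")
    if threshold is None:
        threshold = noise_threshold(counts)
    return counts > threshold


def hough_lines(mask: np.ndarray, theta_step: float = 1.0,
                min_votes: int = DEFAULT_MIN_VOTES,
                max_lines: int = DEFAULT_MAX_LINES,
                nms_window: int = 2) -> list[HoughPeak]:
    """Detect straight lines in a binary mask.

    Peaks are extracted in descending vote order with non-maximum
    suppression of +-``nms_window`` bins along both the theta and rho axes
    (rho bins are 1 px); at most ``max_lines`` peaks with at least
    ``min_votes`` votes are returned. An empty mask yields an empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    thetas = np.deg2rad(np.arange(-90.0, 90.0, theta_step))
    accum, angles, rhos = hough_line(mask, theta=thetas)
    nms = max(1, 2 * int(nms_window) + 1)
    votes, peak_angles, peak_rhos = hough_line_peaks(
        accum, angles, rhos, min_distance=nms, min_angle=nms,
        threshold=max(min_votes, 1), num_peaks=max_lines)
    peaks = []
    for v, a, r in zip(votes, peak_angles, peak_rhos):
        theta_deg = float(np.rad2deg(a))
        peaks.append(HoughPeak(rho=float(r), theta=theta_deg,
                               direction=(theta_deg + 90.0) % 180.0,
                               votes=int(v)))
    return peaks


def wrap_relative(angles_deg: np.ndarray, reference_deg: float) -> np.ndarray:
    """Signed differences to the reference on the 180-deg circle, in (-90, 90]."""
    rel = np.mod(np.asarray(angles_deg, dtype=float) - reference_deg, 180.0)
    return np.where(rel > 90.0, rel - 180.0, rel)


def relative_angles(line_directions: np.ndarray,
                    seed: int | np.random.Generator | None = 0,
                    reference_index: int | None = None,
                    ) -> tuple[int, float, np.ndarray]:
    """Pick a random reference fiber and express the rest relative to it.

    Returns (reference index, reference angle, relative angles of the
    remaining fibers). The reference's own zero angle is excluded.
    """
    dirs = np.asarray(line_directions, dtype=float)
    if dirs.size == 0:
        raise ValueError("need at least one detected fiber")
    if reference_index is None:
        rng = seed if isinstance(seed, np.random.Generator) else \
            np.random.default_rng(seed)
        reference_index = int(rng.integers(dirs.size))
    ref = float(dirs[reference_index])
    rest = np.delete(dirs, reference_index)
    return reference_index, ref, wrap_relative(rest, ref)


def angle_histogram(rel_angles: np.ndarray, bin_width: float = 5.0,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Probability histogram over bins tiling (-90, 90]."""
    rel = np.asarray(rel_angles, dtype=float)
    if rel.size == 0:
        raise ValueError("need at least one angle")
    if not np.isclose(180.0 % bin_width, 0.0):
        adjusted = 180.0 / max(1, round(180.0 / bin_width))
        warnings.warn(f"bin_width {bin_width} does not divide 180; "
                      f"using {adjusted}")
        bin_width = adjusted
    edges = np.arange(-90.0, 90.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(rel, bins=edges)
    return edges, counts / rel.size


def circular_sd_deg(angles_deg: np.ndarray) -> float:
    """Period-180 circular standard deviation in degrees.

    Angles are doubled onto the full circle; sd = sqrt(-2 ln R) / 2 where R
    is the resultant length. Exact for a wrapped normal (returns its sigma)
    and invariant to any common rotation, hence to the reference choice.
    """
    a = np.deg2rad(np.asarray(angles_deg, dtype=float)) * 2.0
    z = np.exp(1j * a).mean()
    r = float(np.abs(z))
    if r >= 1.0 - 1e-15:
        return 0.0
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(r)) / 2.0))


def _fwhm_deg(rel_angles: np.ndarray, bin_width: float = 5.0,
              smooth_sigma_bins: float = 1.0) -> float:
    """Full width at half maximum of the (smoothed) angular histogram."""
    rel = np.asarray(rel_angles, dtype=float)
    if np.allclose(rel, rel.flat[0]):
        return 0.0
    edges, probs = angle_histogram(rel, bin_width=bin_width)
    if smooth_sigma_bins > 0:
        probs = gaussian_filter1d(probs, smooth_sigma_bins, mode="wrap")
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(probs))
    half = probs[peak] / 2.0

    def _cross(i_out, i_in):
        # linear interpolation between the bin centers straddling half-max
        p0, p1 = probs[i_out], probs[i_in]
        if p1 == p0:
            return centers[i_in]
        t = (half - p0) / (p1 - p0)
        return centers[i_out] + t * (centers[i_in] - centers[i_out])

    left = peak
    while left > 0 and probs[left - 1] >= half:
        left -= 1
    right = peak
    last = len(probs) - 1
    while right < last and probs[right + 1] >= half:
        right += 1
    lo = _cross(left - 1, left) if left > 0 else edges[0]
    hi = _cross(right + 1, right) if right < last else edges[-1]
    return float(hi - lo)


def distribution_width(rel_angles: np.ndarray, method: str = "circular_sd",
                       bin_width: float = 5.0,
                       smooth_sigma_bins: float = 1.0) -> float:
    """Angular distribution width in degrees by the chosen method."""
    rel = np.asarray(rel_angles, dtype=float)
    if method == "circular_sd":
        if rel.size < 2:
            raise ValueError("circular_sd needs at least 2 angles")
        return circular_sd_deg(rel)
    if method == "fwhm":
        if rel.size < 1:
            raise ValueError("fwhm needs at least 1 angle")
        return _fwhm_deg(rel, bin_width=bin_width,
                         smooth_sigma_bins=smooth_sigma_bins)
    raise ValueError(f"unknown width method {method!r}")


def refine_direction(counts: np.ndarray, mask: np.ndarray, peak: HoughPeak,
                     band: float = 4.0, iters: int = 5) -> float:
    """Refine one Hough peak by intensity-weighted total least squares.

    The 1-degree accumulator bins leave a flat plateau for short segments;
    fitting the principal direction of the above-threshold pixels within
    ``band`` px of the line, weighted by intensity (the transverse profile
    is symmetric about the centerline), recovers sub-degree accuracy.
    Returns the refined direction in [0, 180).
    """
    ys, xs = np.nonzero(mask)
    if xs.size < 5:
        return peak.direction
    pts = np.column_stack([xs, ys]).astype(float)
    weights = np.asarray(counts, dtype=float)[ys, xs]
    th = math.radians(peak.theta)
    normal = np.array([math.cos(th), math.sin(th)])
    center = peak.rho * normal
    direction = peak.direction
    for _ in range(iters):
        dist = (pts - center) @ normal
        sel = np.abs(dist) <= band
        if int(sel.sum()) < 5:
            break
        w = weights[sel]
        mean = (pts[sel] * w[:, None]).sum(axis=0) / w.sum()
        q = (pts[sel] - mean) * np.sqrt(w)[:, None]
        _, _, vt = np.linalg.svd(q, full_matrices=False)
        v = vt[0]
        direction = math.degrees(math.atan2(v[1], v[0])) % 180.0
        normal = np.array([-v[1], v[0]])
        center = mean
    return float(direction)


def _line_support(skel_pts: np.ndarray, peak: HoughPeak, direction: float,
                  band: float = 1.5, anchor_band: float = 4.0,
                  ) -> tuple[int, float]:
    """Skeleton support of a (refined) line: inlier count and fill fraction.

    The line is anchored at the centroid of the skeleton pixels within
    ``anchor_band`` px of the original Hough line; support counts skeleton
    pixels within ``band`` px of the refined direction through that anchor,
    and fill is support divided by the spanned length along the line. A
    true fiber centerline fills its span (~1); a spurious line bridging
    several parallel fibers only touches them at crossings (fill << 1).
    """
    th = math.radians(peak.theta)
    n0 = np.array([math.cos(th), math.sin(th)])
    sel0 = np.abs(skel_pts @ n0 - peak.rho) <= anchor_band
    if int(sel0.sum()) < 5:
        return 0, 0.0
    center = skel_pts[sel0].mean(axis=0)
    phi = math.radians(direction)
    u = np.array([math.cos(phi), math.sin(phi)])
    n = np.array([-u[1], u[0]])
    d = skel_pts - center
    sel = np.abs(d @ n) <= band
    count = int(sel.sum())
    if count == 0:
        return 0, 0.0
    t = d[sel] @ u
    fill = count / max(float(t.max() - t.min()), 1.0)
    return count, float(fill)


def detect_fiber_directions(image: IntensityImage | np.ndarray,
                            threshold: float | None = None,
                            theta_step: float = 1.0,
                            min_votes: int = DEFAULT_MIN_VOTES,
                            max_lines: int = DEFAULT_MAX_LINES,
                            nms_window: int = 2,
                            min_blob_area: int = 30,
                            refine: bool = True,
                            min_fill: float = 0.5) -> np.ndarray:
    """Detect fiber directions in an image, in degrees in [0, 180).

    Pipeline: binarize (default threshold: the larger of the noise
    threshold and Otsu's threshold, so bright fibers are separated from
    the dim shot-noise halo around them), drop connected components
    smaller than ``min_blob_area`` px, skeletonize to 1-px centerlines,
    vote in the Hough accumulator, refine each peak with an
    intensity-weighted line fit on the cleaned mask, and finally drop
    candidates whose refined line has fewer than ``min_votes`` skeleton
    inliers or a fill fraction below ``min_fill`` (lines bridging several
    distinct fibers). Set ``min_fill=0`` to disable the support filter.
    """
    counts = image.counts if isinstance(image, IntensityImage) else \
        np.asarray(image)
    if threshold is None:
        threshold = max(noise_threshold(counts),
                        float(threshold_otsu(np.asarray(counts, dtype=float))))
    mask = binarize(counts, threshold=threshold)
    if min_blob_area > 1:
        mask = remove_small_objects(mask, max_size=min_blob_area - 1)
    skeleton = skeletonize(mask)
    peaks = hough_lines(skeleton, theta_step=theta_step, min_votes=min_votes,
                        max_lines=max_lines, nms_window=nms_window)
    if not peaks:
        return np.array([], dtype=float)
    ys, xs = np.nonzero(skeleton)
    skel_pts = np.column_stack([xs, ys]).astype(float)
    directions = []
    for p in peaks:
        d = refine_direction(counts, mask, p) if refine else p.direction
        if min_fill > 0:
            support, fill = _line_support(skel_pts, p, d)
            if support < min_votes or fill < min_fill:
                continue
        directions.append(d)
    return np.array(directions, dtype=float)


def analyze_angles(directions_per_image: list[np.ndarray], seed: int = 0,
                   reference_mode: str = "group", bin_width: float = 5.0,
                   width_method: str = "circular_sd") -> FiberAngleSet:
    """Relative-angle distribution of one group's detected fibers.

    ``reference_mode="group"`` (default) draws one reference fiber from the
    pooled directions; ``"image"`` draws a reference per image and pools
    the per-image relative angles.
    """
    kept = [np.asarray(d, dtype=float) for d in directions_per_image
            if np.asarray(d).size > 0]
    if not kept:
        raise ValueError("no fibers detected in any image")
    rng = np.random.default_rng(seed)
    if reference_mode == "group":
        pooled = np.concatenate(kept)
        _, ref, rel = relative_angles(pooled, seed=rng)
    elif reference_mode == "image":
        rels = []
        ref = float("nan")
        for dirs in kept:
            _, ref_i, rel_i = relative_angles(dirs, seed=rng)
            if np.isnan(ref):
                ref = ref_i
            rels.append(rel_i)
        pooled = np.concatenate(kept)
        rel = np.concatenate(rels) if rels else np.array([])
    else:
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    if rel.size == 0:
        raise ValueError("need at least two fibers for a relative-angle set")
    edges, probs = angle_histogram(rel, bin_width=bin_width)
    # group mode: widths use the full fiber set (reference's zero included),
    # so the circular SD is exactly invariant to which fiber was the
    # reference. image mode: widths describe the pooled per-image relative
    # angles themselves.
    rel_full = wrap_relative(pooled, ref) if reference_mode == "group" else rel
    widths = {
        "circular_sd": circular_sd_deg(rel_full),
        "fwhm": _fwhm_deg(rel_full, bin_width=bin_width),
    }
    return FiberAngleSet(directions=pooled, reference_angle=ref,
                         relative_angles=rel, bin_edges=edges,
                         probabilities=probs, width=widths[width_method],
                         width_method=width_method, seed=seed, widths=widths)
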