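"""Synthetic SHG-like phantom images and cohort datasets.

The generator emulates the statistical structure of an SHG microscopy
study of liver collagen: photon-count images are Poisson background plus
bright, straight collagen-fiber segments with a Gaussian transverse
profile. It does not simulate SHG optics (no phase matching, polarization
or forward/backward ratios) — intensity phantoms only, single plane.

The default cohort layout mirrors a four-diet-group design (control C,
arsenic A, sucrose S, arsenic-sucrose AS) with 6 animals per group and 10
high-resolution scans per animal: 240 images in total. Per-group fibrosis
prevalences default to 0.08 / 0.24 / 0.40 / 0.62 and fiber angular
dispersions to 26 / 24 / 16 / 2.8 degrees, so the expected fibrotic split
is 160 non-fibrotic / 80 fibrotic.

Every rendered fiber's orientation is recorded in the manifest, so the
orientation-analysis stage can be validated against ground truth.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .imgio import IntensityImage, LabeledDataset, write_image, write_manifest


@dataclass(frozen=True)
class SynthConfig:
    """Phantom generator parameters.

    The defaults place the analysis noise threshold (one-tenth of the image
    mean under the normalized-DFT convention) strictly below one count for
    both classes: with ``background_rate=0.2`` a non-fibrotic image has
    threshold ~0.02 and a fibrotic one stays below 1.0, so the
    above-threshold pixel fraction reduces to the occupancy of nonzero
    pixels. Fibers then raise that occupancy well past the Poisson
    background level, giving the two classes non-overlapping
    ``frac_above`` distributions (strong class separation).

    Attributes
    ----------
    image_height, image_width : int
        Image size in pixels (one pixel per 10 um scan step).
    background_rate : float
        Mean photon count per background pixel (Poisson).
    fiber_count_range : tuple[int, int]
        Inclusive range of fibers per fibrotic image.
    fiber_length_range : tuple[float, float]
        Fiber length range in pixels.
    fiber_thickness_sigma : float
        Gaussian transverse profile sigma, pixels.
    fiber_peak_amplitude : float
        Counts added at the fiber centerline.
    mean_orientation : float
        Mean fiber orientation, degrees in [0, 180).
    angular_sigma : float
        Wrapped-normal dispersion of orientations, degrees.
    seed : int
        Default seed when none is passed explicitly.
    """

    image_height: int = 100
    image_width: int = 100
    background_rate: float = 0.2
    fiber_count_range: tuple[int, int] = (4, 8)
    fiber_length_range: tuple[float, float] = (30.0, 60.0)
    fiber_thickness_sigma: float = 1.5
    fiber_peak_amplitude: float = 30.0
    mean_orientation: float = 90.0
    angular_sigma: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 20 or self.image_width < 20:
            raise ValueError("image dimensions must be >= 20 pixels")
        if self.background_rate < 0 or self.fiber_peak_amplitude < 0:
            raise ValueError("rates and amplitudes must be >= 0")
        if self.angular_sigma < 0:
            raise ValueError("angular_sigma must be >= 0")
        lo, hi = self.fiber_count_range
        if lo < 1 or hi < lo:
            raise ValueError("fiber_count_range lower bound must be >= 1")
        llo, lhi = self.fiber_length_range
        diag = math.hypot(self.image_height, self.image_width)
        if llo <= 0 or lhi < llo:
            raise ValueError("invalid fiber_length_range")
        if lhi > diag:
            raise ValueError(f"fiber length {lhi} exceeds image diagonal {diag:.1f}")


@dataclass(frozen=True)
class CohortSpec:
    """One diet group: animals, scans per animal, prevalence and dispersion."""

    group_name: str
    n_animals: int = 6
    images_per_animal: int = 10
    fibrosis_prevalence: float = 0.0
    angular_sigma: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fibrosis_prevalence <= 1.0:
            raise ValueError("fibrosis_prevalence must lie in [0, 1]")
        if self.n_animals < 1 or self.images_per_animal < 1:
            raise ValueError("cohort must contain at least one image")


def default_cohorts() -> list[CohortSpec]:
    """The four-group study layout (prevalences and angular dispersions)."""
    return [
        CohortSpec("C", 6, 10, 0.08, 26.0),
        CohortSpec("A", 6, 10, 0.24, 24.0),
        CohortSpec("S", 6, 10, 0.40, 16.0),
        CohortSpec("AS", 6, 10, 0.62, 2.8),
    ]


def wrapped_normal_angles(rng: np.random.Generator, mean_deg: float,
                          sigma_deg: float, size: int) -> np.ndarray:
    """Sample fiber orientations from a wrapped normal on the 180-deg circle."""
    return np.mod(rng.normal(mean_deg, sigma_deg, size), 180.0)


def _render_fiber(h: int, w: int, cx: float, cy: float, angle_deg: float,
                  length: float, sigma: float, amplitude: float) -> np.ndarray:
    """Additive intensity field of one straight fiber segment.

    The segment runs through (cx, cy) along ``angle_deg`` (CCW from the
    +x/column axis in the (col,row) frame); the transverse profile is
    Gaussian with the given sigma, with matching Gaussian soft end caps.
    """
    phi = math.radians(angle_deg)
    dx, dy = math.cos(phi), math.sin(phi)
    x0, y0 = cx - dx * length / 2, cy - dy * length / 2
    x1, y1 = cx + dx * length / 2, cy + dy * length / 2
    cols = np.arange(w, dtype=float)
    rows = np.arange(h, dtype=float)
    X, Y = np.meshgrid(cols, rows)
    vx, vy = x1 - x0, y1 - y0
    seg2 = vx * vx + vy * vy
    t = ((X - x0) * vx + (Y - y0) * vy) / seg2
    t = np.clip(t, 0.0, 1.0)
    px = x0 + t * vx
    py = y0 + t * vy
    d2 = (X - px) ** 2 + (Y - py) ** 2
    return amplitude * np.exp(-d2 / (2.0 * sigma * sigma))


def generate_image(config: SynthConfig, fibrotic: bool,
                   seed: int | np.random.Generator | None = None,
                   **metadata) -> IntensityImage:
    """Generate one phantom image.

    Non-fibrotic images are pure Poisson background; fibrotic images add k
    fibers (k uniform on ``fiber_count_range``) whose orientations are
    wrapped-normal draws. Rendered orientations are stored on the returned
    image's ``fiber_angles``. Identical (config, seed) gives an identical
    image.
    """
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(config.seed if seed is None else seed)
    h, w = config.image_height, config.image_width
    counts = rng.poisson(config.background_rate, size=(h, w)).astype(np.int64)
    angles: tuple[float, ...] = ()
    if fibrotic:
        lo, hi = config.fiber_count_range
        k = int(rng.integers(lo, hi + 1))
        thetas = wrapped_normal_angles(rng, config.mean_orientation,
                                       config.angular_sigma, k)
        field = np.zeros((h, w), dtype=float)
        for theta in thetas:
            length = rng.uniform(*config.fiber_length_range)
            # place the segment fully inside the frame so the recorded
            # orientation is the orientation of the visible fiber
            phi = math.radians(theta)
            dx = abs(math.cos(phi)) * length / 2
            dy = abs(math.sin(phi)) * length / 2
            cx = rng.uniform(min(dx, (w - 1) / 2), max(w - 1 - dx, (w - 1) / 2))
            cy = rng.uniform(min(dy, (h - 1) / 2), max(h - 1 - dy, (h - 1) / 2))
            field += _render_fiber(h, w, cx, cy, theta, length,
                                   config.fiber_thickness_sigma,
                                   config.fiber_peak_amplitude)
        counts += np.rint(field).astype(np.int64)
        angles = tuple(float(t) for t in thetas)
    return IntensityImage(counts=counts, fiber_angles=angles, **metadata)


def _fibrotic_count(rng: np.random.Generator, prevalence: float, m: int) -> int:
    """Per-animal fibrotic image count: integer part plus Bernoulli remainder.

    round-with-stochastic-remainder keeps the expectation exactly
    prevalence*m while giving a nonzero between-animal SD.
    """
    x = prevalence * m
    base = int(math.floor(x))
    frac = x - base
    n = base + (1 if rng.random() < frac else 0)
    return min(n, m)


def generate_dataset(cohorts: list[CohortSpec] | None = None,
                     config: SynthConfig | None = None,
                     seed: int = 0,
                     outdir: str | Path | None = None,
                     image_format: str = "tiff") -> LabeledDataset:
    """Generate a full cohort dataset with manifest.

    One image per (group, animal, scan) slot. Per-group angular dispersion
    overrides ``config.angular_sigma``. If *outdir* is given the images and
    ``manifest.csv`` are written there (images under ``images/``).
    """
    if cohorts is None:
        cohorts = default_cohorts()
    if not cohorts:
        raise ValueError("cohort list must be non-empty")
    if config is None:
        config = SynthConfig()

    ss = np.random.SeedSequence(seed)
    split_rng = np.random.default_rng(ss.spawn(1)[0])
    images: list[IntensityImage] = []
    rows = []
    ext = {"tiff": ".tiff", "png": ".png", "text": ".txt"}[image_format]
    child_iter = iter(ss.spawn(sum(c.n_animals * c.images_per_animal
                                   for c in cohorts)))
    for cohort in cohorts:
        cfg = dataclasses.replace(config, angular_sigma=cohort.angular_sigma)
        for a in range(cohort.n_animals):
            animal = f"{cohort.group_name}{a + 1}"
            n_fib = _fibrotic_count(split_rng, cohort.fibrosis_prevalence,
                                    cohort.images_per_animal)
            slots = split_rng.permutation(cohort.images_per_animal)
            fibrotic_slots = set(slots[:n_fib].tolist())
            for s in range(cohort.images_per_animal):
                image_id = f"{animal}_{s + 1:02d}"
                fib = s in fibrotic_slots
                img = generate_image(
                    cfg, fibrotic=fib,
                    seed=np.random.default_rng(next(child_iter)),
                    image_id=image_id, group=cohort.group_name, animal=animal,
                )
                images.append(img)
                rows.append({
                    "image_id": image_id,
                    "path": f"images/{image_id}{ext}",
                    "group": cohort.group_name,
                    "animal": animal,
                    "label": int(fib),
                    "fiber_angles_deg": img.fiber_angles,
                })
    manifest = pd.DataFrame(rows)
    dataset = LabeledDataset(images=images, manifest=manifest)
    if outdir is not None:
        write_dataset(dataset, outdir, image_format=image_format)
    return dataset


def write_dataset(dataset: LabeledDataset, outdir: str | Path,
                  image_format: str = "tiff") -> Path:
    """Write all images plus ``manifest.csv`` under *outdir*."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    for img, path in zip(dataset.images, dataset.manifest["path"]):
        write_image(img, outdir / path, fmt=image_format)
    write_manifest(dataset.manifest, outdir / "manifest.csv")
    return outdir
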