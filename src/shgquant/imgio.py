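"""Image and manifest input/output.

Single source of truth for pixel-coordinate and file-format conventions:

* arrays are indexed ``[row, col]``, 0-based, origin at the top-left corner,
  row index increasing downward, column index increasing rightward;
* angles are measured counter-clockwise from the +x (column) axis in the
  ``(x=col, y=row)`` frame, on the period-180 orientation circle;
* photon counts are non-negative integers; 16-bit on disk (values above
  65535 are an error, never silently clipped).

Supported formats: uncompressed 16-bit grayscale TIFF (default), 16-bit
grayscale PNG, and whitespace-delimited integer text matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Minimum image side length: one 20x20 analysis window must fit.
MIN_SIZE = 20

#: Diet groups of the study design: control, arsenic, sucrose, arsenic-sucrose.
KNOWN_GROUPS = ("C", "A", "S", "AS")

MANIFEST_COLUMNS = ("image_id", "path", "group", "animal", "label", "fiber_angles_deg")


@dataclass
class IntensityImage:
    """A single-channel photon-count image with acquisition metadata.

    Parameters
    ----------
    counts
        H x W matrix of non-negative integer photon counts (counts per
        100 ps detection gate; the absolute scale is arbitrary).
    pixel_pitch
        Scan step in micrometres per pixel (default 10).
    image_id, group, animal
        Identifiers carried through the manifest.
    fiber_angles
        Ground-truth fiber orientations in degrees, populated by the
        synthetic generator (empty for real or non-fibrotic images).
    """

    counts: np.ndarray
    pixel_pitch: float = 10.0
    image_id: str = ""
    group: str | None = None
    animal: str | None = None
    fiber_angles: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        validate_counts(self.counts, min_size=1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape  # type: ignore[return-value]


@dataclass
class LabeledDataset:
    """Images plus manifest metadata and binary fibrosis labels."""

    images: list[IntensityImage]
    manifest: pd.DataFrame

    def __len__(self) -> int:
        return len(self.images)

    @property
    def labels(self) -> np.ndarray:
        return self.manifest["label"].to_numpy(dtype=int)


def validate_counts(counts: np.ndarray, min_size: int = MIN_SIZE) -> None:
    """Raise ``ValueError`` if *counts* is not a valid count matrix."""
    if counts.ndim != 2:
        raise ValueError(f"single-channel required: got array of ndim {counts.ndim}")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.all(counts == np.round(counts)):
            raise ValueError("photon counts must be integers")
    if counts.size and counts.min() < 0:
        raise ValueError("photon counts must be non-negative")
    h, w = counts.shape
    if h < min_size or w < min_size:
        raise ValueError(f"image {h}x{w} smaller than minimum size {min_size}")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix == ".png":
        return "png"
    if suffix in (".txt", ".dat"):
        return "text"
    raise ValueError(f"cannot infer image format from suffix {suffix!r}")


def write_image(image: IntensityImage | np.ndarray, path: str | Path,
                fmt: str | None = None) -> Path:
    """Write a count matrix to disk (16-bit grayscale or text matrix)."""
    path = Path(path)
    counts = image.counts if isinstance(image, IntensityImage) else np.asarray(image)
    validate_counts(counts, min_size=1)
    fmt = _infer_format(path, fmt)
    if fmt in ("tiff", "png"):
        if counts.size and counts.max() > 65535:
            raise ValueError(
                f"count {int(counts.max())} exceeds 16-bit range; refusing to clip"
            )
        data = counts.astype(np.uint16)
        if fmt == "tiff":
            tifffile.imwrite(path, data, compression=None)
        else:
            iio.imwrite(path, data, extension=".png")
    elif fmt == "text":
        np.savetxt(path, counts.astype(np.int64), fmt="%d")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_image(path: str | Path, fmt: str | None = None, min_size: int = MIN_SIZE,
               **metadata) -> IntensityImage:
    """Read a single-channel count image; lossless for 16-bit integer data."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "tiff":
        counts = tifffile.imread(path)
    elif fmt == "png":
        counts = iio.imread(path)
    elif fmt == "text":
        counts = np.loadtxt(path, dtype=np.int64, ndmin=2)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError(f"single-channel required: {path} has shape {counts.shape}")
    validate_counts(counts, min_size=min_size)
    return IntensityImage(counts=counts.astype(np.int64), **metadata)


def _format_angles(angles) -> str:
    return ";".join(f"{a:.6g}" for a in angles)


def _parse_angles(cell) -> tuple[float, ...]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return ()
    return tuple(float(tok) for tok in str(cell).split(";"))


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    """Write the manifest CSV (fiber angles serialized semicolon-separated)."""
    path = Path(path)
    out = manifest.copy()
    if len(out) and not isinstance(out["fiber_angles_deg"].iloc[0], str):
        out["fiber_angles_deg"] = out["fiber_angles_deg"].map(_format_angles)
    out.to_csv(path, index=False, columns=list(MANIFEST_COLUMNS))
    return path


def read_manifest(path: str | Path, images_root: str | Path | None = None,
                  load_images: bool = True, min_size: int = MIN_SIZE,
                  allowed_groups: tuple[str, ...] | None = KNOWN_GROUPS,
                  ) -> LabeledDataset:
    """Load a manifest CSV and (optionally) the images it references.

    Every row must resolve to a readable image when ``load_images`` is true;
    labels are mapped to {0 = non-fibrotic, 1 = fibrotic}.
    """
    path = Path(path)
    root = Path(images_root) if images_root is not None else path.parent
    df = pd.read_csv(path, dtype={"image_id": str, "group": str, "animal": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if len(df) == 0:
        logger.warning("manifest %s has a header but no rows", path)
        return LabeledDataset(images=[], manifest=df)
    dupes = df["image_id"][df["image_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate image_id(s): {sorted(set(dupes))}")
    if allowed_groups is not None:
        unknown = set(df["group"]) - set(allowed_groups)
        if unknown:
            raise ValueError(f"unknown group tag(s): {sorted(unknown)}")
    labels = df["label"].astype(int)
    if not labels.isin((0, 1)).all():
        raise ValueError("labels must be 0 (non-fibrotic) or 1 (fibrotic)")
    df["label"] = labels
    df["fiber_angles_deg"] = df["fiber_angles_deg"].map(_parse_angles)

    images: list[IntensityImage] = []
    if load_images:
        for i, row in df.iterrows():
            img_path = root / row["path"]
            if not img_path.exists():
                raise FileNotFoundError(
                    f"manifest row {i} (image_id={row['image_id']}): "
                    f"missing file {img_path}"
                )
            images.append(read_image(
                img_path, min_size=min_size, image_id=row["image_id"],
                group=row["group"], animal=row["animal"],
                fiber_angles=row["fiber_angles_deg"],
            ))
    return LabeledDataset(images=images, manifest=df)
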