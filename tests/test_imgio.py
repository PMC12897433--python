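"""Image and manifest I/O round-trips and validation."""

import numpy as np
import pandas as pd
import pytest

from shgquant.imgio import (IntensityImage, read_image, read_manifest,
                            validate_counts, write_image, write_manifest)


@pytest.mark.parametrize("fmt,suffix", [("tiff", ".tiff"), ("png", ".png"),
                                        ("text", ".txt")])
def test_image_roundtrip(tmp_path, rng, fmt, suffix):
    counts = rng.integers(0, 1000, size=(25, 30))
    path = tmp_path / f"img{suffix}"
    write_image(counts, path, fmt=fmt)
    back = read_image(path)
    assert back.counts.shape == (25, 30)
    np.testing.assert_array_equal(back.counts, counts)
    assert np.issubdtype(back.counts.dtype, np.integer)


def test_format_inferred_from_suffix(tmp_path, rng):
    counts = rng.integers(0, 10, size=(20, 20))
    path = tmp_path / "a.tif"
    write_image(counts, path)
    np.testing.assert_array_equal(read_image(path).counts, counts)


def test_overflow_refused(tmp_path):
    counts = np.full((20, 20), 70000, dtype=np.int64)
    with pytest.raises(ValueError, match="16-bit"):
        write_image(counts, tmp_path / "a.tiff")
    # text format carries arbitrary integers
    write_image(counts, tmp_path / "a.txt")
    np.testing.assert_array_equal(read_image(tmp_path / "a.txt").counts, counts)


def test_validate_counts_errors():
    with pytest.raises(ValueError, match="single-channel"):
        validate_counts(np.zeros((5, 5, 3), dtype=int))
    with pytest.raises(ValueError, match="non-negative"):
        validate_counts(np.full((20, 20), -1))
    with pytest.raises(ValueError, match="integer"):
        validate_counts(np.full((20, 20), 0.5))
    with pytest.raises(ValueError, match="smaller than minimum"):
        validate_counts(np.zeros((10, 10), dtype=int))
    validate_counts(np.zeros((20, 20), dtype=int))  # ok


def test_intensity_image_validates():
    with pytest.raises(ValueError):
        IntensityImage(counts=np.full((5, 5), -3))


def _manifest_row(image_id, path, group="C", animal="C1", label=0, angles=""):
    return {"image_id": image_id, "path": path, "group": group,
            "animal": animal, "label": label, "fiber_angles_deg": angles}


def test_manifest_roundtrip(tmp_path, rng):
    (tmp_path / "images").mkdir()
    rows = []
    for i in range(3):
        counts = rng.integers(0, 50, size=(20, 20))
        write_image(counts, tmp_path / "images" / f"im{i}.tiff")
        rows.append(_manifest_row(f"im{i}", f"images/im{i}.tiff",
                                  label=i % 2,
                                  angles=(10.5, 90.0) if i % 2 else ()))
    write_manifest(pd.DataFrame(rows), tmp_path / "manifest.csv")
    ds = read_manifest(tmp_path / "manifest.csv")
    assert len(ds) == 3
    assert list(ds.labels) == [0, 1, 0]
    assert ds.images[1].fiber_angles == (10.5, 90.0)
    assert ds.images[0].fiber_angles == ()


def test_manifest_duplicate_id_rejected(tmp_path, rng):
    write_image(rng.integers(0, 5, size=(20, 20)), tmp_path / "a.tiff")
    rows = [_manifest_row("x", "a.tiff"), _manifest_row("x", "a.tiff")]
    write_manifest(pd.DataFrame(rows), tmp_path / "m.csv")
    with pytest.raises(ValueError, match="duplicate image_id"):
        read_manifest(tmp_path / "m.csv")


def test_manifest_unknown_group_rejected(tmp_path, rng):
    write_image(rng.integers(0, 5, size=(20, 20)), tmp_path / "a.tiff")
    rows = [_manifest_row("x", "a.tiff", group="Z")]
    write_manifest(pd.DataFrame(rows), tmp_path / "m.csv")
    with pytest.raises(ValueError, match="unknown group"):
        read_manifest(tmp_path / "m.csv")
    # but any tag is allowed when the check is disabled
    ds = read_manifest(tmp_path / "m.csv", allowed_groups=None)
    assert ds.manifest["group"].iloc[0] == "Z"


def test_manifest_missing_file_rejected(tmp_path):
    rows = [_manifest_row("x", "nope.tiff")]
    write_manifest(pd.DataFrame(rows), tmp_path / "m.csv")
    with pytest.raises(FileNotFoundError, match="nope.tiff"):
        read_manifest(tmp_path / "m.csv")


def test_manifest_empty_warns(tmp_path, caplog):
    write_manifest(pd.DataFrame(columns=["image_id", "path", "group", "animal",
                                         "label", "fiber_angles_deg"]),
                   tmp_path / "m.csv")
    with caplog.at_level("WARNING"):
        ds = read_manifest(tmp_path / "m.csv")
    assert len(ds) == 0
    assert any("no rows" in r.message for r in caplog.records)


def test_manifest_missing_column_rejected(tmp_path):
    pd.DataFrame({"image_id": ["a"]}).to_csv(tmp_path / "m.csv", index=False)
    with pytest.raises(ValueError, match="missing columns"):
        read_manifest(tmp_path / "m.csv")
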