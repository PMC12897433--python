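"""Per-diet-group fibrosis summaries.

Maps per-image fibrosis predictions back to diet groups and animals and
produces mean +- SD percentage tables: for each animal the percentage of
its images classified fiber-positive, then the mean and sample SD (n-1
denominator) of those percentages across the group's animals. The animal
is the unit of replication; a per-image bootstrap SD is available as an
alternative.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GroupSummary:
    """One diet group's fiber-positive percentages."""

    group: str
    per_animal_pct: list[float]
    mean_pct: float
    sd_pct: float
    n_images: int
    n_animals: int


def group_fiber_percentages(predictions: pd.Series | dict,
                            manifest: pd.DataFrame,
                            sd_unit: str = "animal",
                            bootstrap_reps: int = 1000,
                            seed: int = 0) -> list[GroupSummary]:
    """Summarize hard fibrosis predictions per diet group.

    *predictions* maps image_id -> 0/1. With ``sd_unit="animal"`` (default)
    the SD is across per-animal percentages; ``"image"`` uses a per-image
    bootstrap within the group.
    """
    pred = pd.Series(predictions)
    missing = set(pred.index) - set(manifest["image_id"])
    if missing:
        raise ValueError(f"predicted image(s) not in manifest: {sorted(missing)[:5]}")
    df = manifest.loc[:, ["image_id", "group", "animal"]].copy()
    df = df[df["image_id"].isin(pred.index)]
    if df.empty:
        raise ValueError("no predicted image appears in the manifest")
    df["positive"] = df["image_id"].map(pred).astype(int)

    rng = np.random.default_rng(seed)
    summaries: list[GroupSummary] = []
    for group, gdf in df.groupby("group", sort=False):
        if len(gdf) == 0:
            raise ValueError(f"group {group} has zero images")
        per_animal = []
        for animal, adf in gdf.groupby("animal", sort=True):
            if len(adf) == 0:
                raise ValueError(f"animal {animal} has zero images")
            per_animal.append(100.0 * adf["positive"].mean())
        mean_pct = float(np.mean(per_animal))
        if sd_unit == "animal":
            sd_pct = float(np.std(per_animal, ddof=1)) if len(per_animal) > 1 \
                else 0.0
        elif sd_unit == "image":
            pos = gdf["positive"].to_numpy()
            boots = [100.0 * rng.choice(pos, size=pos.size).mean()
                     for _ in range(bootstrap_reps)]
            sd_pct = float(np.std(boots, ddof=1))
        else:
            raise ValueError(f"unknown sd_unit {sd_unit!r}")
        summaries.append(GroupSummary(
            group=str(group), per_animal_pct=per_animal, mean_pct=mean_pct,
            sd_pct=sd_pct, n_images=len(gdf),
            n_animals=gdf["animal"].nunique()))
    return summaries


def summaries_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "group": s.group, "mean_pct": s.mean_pct, "sd_pct": s.sd_pct,
        "n_images": s.n_images, "n_animals": s.n_animals,
    } for s in summaries])


def render_report(summaries: list[GroupSummary],
                  widths: dict[str, float] | None = None,
                  ) -> tuple[pd.DataFrame, str]:
    """CSV-ready frame plus a human-readable mean +- SD report.

    *widths* optionally maps group -> angular distribution width (degrees);
    the width section is omitted with a notice when absent or empty.
    """
    if not summaries:
        raise ValueError("no group summaries to render")
    frame = summaries_frame(summaries)
    if widths:
        frame["width_deg"] = frame["group"].map(widths)

    buf = io.StringIO()
    buf.write("Percentage of images containing collagen fibers (mean ± SD)\n")
    for s in summaries:
        buf.write(f"  {s.group}: {s.mean_pct:.1f} ± {s.sd_pct:.1f}%"
                  f"  ({s.n_animals} animals, {s.n_images} images)\n")
    buf.write("\nAngular distribution width of fiber orientations\n")
    if widths:
        for group, w in widths.items():
            buf.write(f"  {group}: {w:.1f}°\n")
    else:
        buf.write("  (no width measurements provided)\n")
    return frame, buf.getvalue()
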