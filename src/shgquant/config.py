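"""Flat key-value pipeline configuration.

The config file is plain YAML with only scalar or comma-separated values
(documented below); unknown keys are rejected before any stage runs, and
each pipeline run writes the fully resolved configuration next to its
outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .synth import CohortSpec, SynthConfig

STAGES = ("simulate", "features", "select", "cluster", "cv", "angles", "report")


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end pipeline, with study defaults."""

    outdir: str = "shgquant_run"
    seed: int = 0
    log_level: str = "INFO"

    # synthetic dataset
    image_height: int = 100
    image_width: int = 100
    background_rate: float = 0.2
    fiber_count_min: int = 4
    fiber_count_max: int = 8
    fiber_length_min: float = 30.0
    fiber_length_max: float = 60.0
    fiber_thickness_sigma: float = 1.5
    fiber_peak_amplitude: float = 30.0
    mean_orientation: float = 90.0
    image_format: str = "tiff"
    groups: str = "C,A,S,AS"
    n_animals: int = 6
    images_per_animal: int = 10
    prevalences: str = "0.08,0.24,0.40,0.62"
    angular_sigmas: str = "26,24,16,2.8"

    # features
    window_size: int = 20
    window_stride: int = 10
    factor_window: float = 0.15
    factor_image: float = 1.0

    # random-forest selection
    n_trees: int = 100
    max_depth: int = 0            # 0 = unlimited
    select_max_rows: int = 20000  # subsample cap for the window table

    # k-means
    kmeans_max_iter: int = 500
    kmeans_tol: float = 1e-6
    kmeans_standardize: bool = True
    n_init: int = 1

    # classifier / CV
    lr: float = 0.05
    epochs: int = 500
    k_folds: int = 20
    cv_features: str = "frac_above"
    stratified: bool = True

    # orientation
    theta_step: float = 1.0
    bin_width: float = 5.0
    width_method: str = "circular_sd"
    min_votes: int = 0            # 0 = derive from fiber_length_min
    max_lines: int = 25
    nms_window: int = 2
    reference_mode: str = "group"

    # cohort report
    sd_unit: str = "animal"

    def cohorts(self) -> list[CohortSpec]:
        names = [g.strip() for g in self.groups.split(",") if g.strip()]
        prevs = [float(x) for x in str(self.prevalences).split(",")]
        sigmas = [float(x) for x in str(self.angular_sigmas).split(",")]
        if not (len(names) == len(prevs) == len(sigmas)):
            raise ValueError("groups, prevalences and angular_sigmas must "
                             "have equal length")
        return [CohortSpec(n, self.n_animals, self.images_per_animal, p, s)
                for n, p, s in zip(names, prevs, sigmas)]

    def synth_config(self) -> SynthConfig:
        return SynthConfig(
            image_height=self.image_height, image_width=self.image_width,
            background_rate=self.background_rate,
            fiber_count_range=(self.fiber_count_min, self.fiber_count_max),
            fiber_length_range=(self.fiber_length_min, self.fiber_length_max),
            fiber_thickness_sigma=self.fiber_thickness_sigma,
            fiber_peak_amplitude=self.fiber_peak_amplitude,
            mean_orientation=self.mean_orientation, seed=self.seed,
        )

    def effective_min_votes(self) -> int:
        if self.min_votes > 0:
            return self.min_votes
        return max(1, int(round(0.5 * self.fiber_length_min)))

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        child = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        return int(child[STAGES.index(stage)].generate_state(1)[0] % 2**31)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a flat YAML config, rejecting unknown keys, then apply overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a flat key-value mapping")
        data.update(loaded)
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**data)


def dump_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    return path
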