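"""Shared fixtures for the shgquant test suite."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import shgquant as sq


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohorts():
    """Tiny two-group layout for fast pipeline-level tests."""
    return [
        sq.CohortSpec("C", 2, 3, 0.0, 26.0),
        sq.CohortSpec("AS", 2, 3, 1.0, 2.8),
    ]


@pytest.fixture(scope="session")
def small_dataset(small_cohorts):
    return sq.generate_dataset(small_cohorts, seed=7)


@pytest.fixture(scope="session")
def fibrotic_image():
    return sq.generate_image(sq.SynthConfig(), fibrotic=True, seed=11,
                             image_id="fib", group="AS", animal="AS1")


@pytest.fixture(scope="session")
def background_image():
    return sq.generate_image(sq.SynthConfig(), fibrotic=False, seed=13,
                             image_id="bg", group="C", animal="C1")


@pytest.fixture(scope="session")
def single_fiber_config():
    return dataclasses.replace(sq.SynthConfig(), fiber_count_range=(1, 1))
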