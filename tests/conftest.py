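"""Shared fixtures: synthetic cohorts and fitted pipeline results.

The default cohort (study-scale: 30 controls + 33 subjects, 3 readers,
2-3 repeats, both sides) and its per-side pipeline results are expensive
enough to share at session scope; the seed is fixed so every test sees the
same cohort.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from hippomorph import SimulationConfig, generate_cohort
from hippomorph.pipeline import run_side
from hippomorph.synthetic import LatentMode

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    cohort, truth = generate_cohort(default_config)
    return cohort, truth


@pytest.fixture(scope="session")
def left_result(default_cohort):
    cohort, _ = default_cohort
    return run_side(cohort, "left", M_max=10, seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def right_result(default_cohort):
    cohort, _ = default_cohort
    return run_side(cohort, "right", M_max=10, seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def null_config(default_config):
    """Default structure but zero group effect (both groups share means)."""
    modes = tuple(
        LatentMode(m.name, m.control_mean, m.control_mean, m.sd)
        for m in default_config.latent_modes
    )
    return dataclasses.replace(default_config, latent_modes=modes)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, reduced cohort for I/O and CLI tests."""
    config = SimulationConfig(seed=3, n_controls=4, n_subjects=4, n_readers=2)
    cohort, truth = generate_cohort(config)
    return cohort, truth


def circle_points(n: int, radius: float = 10.0, phase: float = 0.0) -> np.ndarray:
    th = phase + 2 * np.pi * np.arange(n) / n
    return radius * np.column_stack([np.cos(th), np.sin(th)])
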