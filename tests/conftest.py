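"""Shared fixtures: one default synthetic heart reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import curvemorph as cm


@pytest.fixture(scope="session")
def default_cfg() -> cm.GeneratorConfig:
    return cm.GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def default_heart(default_cfg):
    """(heart, cells) for the default 48 hpf wild-type configuration."""
    return cm.generate_heart(default_cfg)


@pytest.fixture(scope="session")
def default_boundaries(default_heart):
    heart, _ = default_heart
    return cm.build_region_boundaries(cm.locate_landmarks(heart))


@pytest.fixture(scope="session")
def default_assignment(default_heart, default_boundaries):
    _, cells = default_heart
    return cm.assign_cells(cells, default_boundaries)


@pytest.fixture(scope="session")
def default_morphometrics(default_heart, default_assignment):
    _, cells = default_heart
    return cm.measure_cells(cells, default_assignment)


@pytest.fixture(scope="session")
def clean_cfg() -> cm.GeneratorConfig:
    """Noise-free, background-free configuration for exact round trips."""
    return cm.GeneratorConfig(seed=1, noise_sd=0.0, background=0.0,
                              intensity_jitter=0.0)


@pytest.fixture(scope="session")
def clean_heart(clean_cfg):
    return cm.generate_heart(clean_cfg)


def make_prism_cell(apical: np.ndarray, basal: np.ndarray,
                    cell_id: str = "t0") -> cm.Cardiomyocyte:
    """Bare prism cell for morphometrics unit tests."""
    return cm.Cardiomyocyte(cell_id=cell_id, apical_outline=apical,
                            basal_outline=basal)
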