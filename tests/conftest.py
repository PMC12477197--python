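"""Shared fixtures: all data is generated programmatically at test time.

The expensive default-scale cohort (58/25/89 samples, 30-40 replicate
spectra each, 1 cm^-1 grid) is built once per session and shared by the
generator-fidelity and preprocessing-contract tests. Model-level tests
use a scaled-down cohort on a coarse 4 cm^-1 grid ending at 2800 cm^-1
(the QC rule needs the 1800-2600 cm^-1 silent region covered).
"""

from __future__ import annotations

import numpy as np
import pytest

from ramanembryo.datatypes import dataset_to_matrix
from ramanembryo.preprocess import PreprocessConfig, preprocess_dataset
from ramanembryo.synth import (GeneratorConfig, default_peak_templates,
                               generate_dataset)

SMALL_GRID = (300.0, 2800.0, 4.0)


def small_generator_config(**overrides) -> GeneratorConfig:
    defaults = dict(group_sizes=(14, 10, 16), spectra_per_sample=(5, 7),
                    grid=SMALL_GRID, spike_rate=0.1, sample_cv=0.05, seed=3)
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def fingerprint_templates(separability: float = 2.0):
    """Default templates restricted below 1750 cm^-1 (fits the small grid's
    signal band; the CH-stretch pair is irrelevant for the ML tests)."""
    return [t for t in default_peak_templates(separability) if t.position < 1750]


@pytest.fixture(scope="session")
def default_dataset():
    """Full-scale cohort at the default generator settings, seed 0."""
    return generate_dataset(GeneratorConfig(seed=0), default_peak_templates())


@pytest.fixture(scope="session")
def default_processed(default_dataset):
    """The same cohort through the full preprocessing pipeline."""
    processed, reports = preprocess_dataset(default_dataset, PreprocessConfig())
    return processed, reports


@pytest.fixture(scope="session")
def ml_data():
    """Scaled-down, well-separated, preprocessed cohort plus its matrix."""
    ds = generate_dataset(small_generator_config(), fingerprint_templates(2.0))
    cfg = PreprocessConfig(range=SMALL_GRID[:2], step=SMALL_GRID[2])
    processed, _ = preprocess_dataset(ds, cfg)
    X, y, sids = dataset_to_matrix(processed)
    return {"samples": processed, "X": X, "y": y, "sample_ids": sids}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
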