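"""Shared fixtures: small synthetic scenarios and a trained classifier.

Session-scoped fixtures keep the expensive pieces (movie rendering,
classifier training) to one run for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from spotlink.cnn import train_classifier
from spotlink.config import Config, DetectParams, LinkParams, ScenarioParams
from spotlink.synthetic import render_training_patches, simulate


@pytest.fixture(scope="session")
def small_scenario() -> ScenarioParams:
    """A quick, easy scenario: few bright particles on a small frame."""
    return ScenarioParams(
        T=30, H=128, W=128, n_particles=5, snr=7.0, n_distractors=3,
        motion="directed", speed_px=1.5, seed=42,
    )


@pytest.fixture(scope="session")
def small_movie(small_scenario):
    return simulate(small_scenario)


@pytest.fixture(scope="session")
def trained_model(small_scenario):
    """Classifier trained on a few hundred patches of the small scenario."""
    patches = render_training_patches(small_scenario, 150, 150, roi_px=16)
    return train_classifier(patches.patches, patches.labels, epochs=15, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def default_config() -> Config:
    return Config()
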