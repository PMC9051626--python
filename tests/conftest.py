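"""Shared fixtures: synthetic worlds and trained models are session-scoped
because world generation and %rank calibration dominate test runtime."""

import numpy as np
import pytest
from hypothesis import settings

from phlaii import pipeline
from phlaii.synth import SynthConfig, generate_world

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def world():
    """Default-conditions world: contaminants, localization noise, 10 samples."""
    return generate_world(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def models(world):
    """Discovery models trained on unmodified monoallelic ligand cores."""
    return pipeline.discovery_models_from_world(world, calibration_n=1000, seed=12)


@pytest.fixture(scope="session")
def discovery(world, models):
    """Filter + assignment of the default world's PSM table."""
    return pipeline.run_discovery(world.psms, world.manifests, models)


@pytest.fixture(scope="session")
def noiseless_world():
    """World in which every PSM is a confidently identified planted ligand."""
    return generate_world(SynthConfig.noiseless(seed=21))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
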