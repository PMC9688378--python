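import warnings

import numpy as np
import pytest
from hypothesis import settings

from betadesync.pipeline import PipelineConfig, run_all

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from betadesync.simulate import NeuralSimConfig
from betadesync.task import TrialTimeline
from betadesync.tfr import MorletConfig

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def timeline() -> TrialTimeline:
    return TrialTimeline()


@pytest.fixture(scope="session")
def small_neural() -> NeuralSimConfig:
    """Tiny cohort for structural checks: 2 per group, 3 trials/condition."""
    return NeuralSimConfig(n_per_group=2, n_trials=3, seed=42)


@pytest.fixture(scope="session")
def fast_morlet() -> MorletConfig:
    return MorletConfig(n_freqs=17, decim=8)


@pytest.fixture(scope="session")
def default_study():
    """One full default study, shared by the directional acceptance checks."""
    return run_all(PipelineConfig(master_seed=7))


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
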