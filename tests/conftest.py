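import numpy as np
import pytest

from mothtaxis import (
    AnalysisConfig, ArenaConfig, ClassifyConfig, LikelihoodConfig,
    MothPolicyConfig, PipelineConfig, PlumeConfig,
)
from mothtaxis.belief import BeliefGrid


@pytest.fixture
def arena():
    return ArenaConfig()


@pytest.fixture
def plume_cfg():
    return PlumeConfig()


@pytest.fixture
def policy_cfg():
    return MothPolicyConfig()


@pytest.fixture
def likelihood():
    return LikelihoodConfig()


@pytest.fixture
def classify_cfg():
    return ClassifyConfig()


@pytest.fixture
def analysis_cfg():
    return AnalysisConfig()


@pytest.fixture
def short_arena():
    """Small fast arena: 10 s trials, coarse but valid geometry."""
    return ArenaConfig(time_limit=10.0)


@pytest.fixture
def small_grid():
    """Tiny belief lattice (8 x 5 cells of 10 mm) for exact/oracle tests."""
    arena = ArenaConfig(length_x=80.0, width_y=50.0)
    return BeliefGrid.uniform(arena, 10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pipeline_cfg():
    return PipelineConfig()
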