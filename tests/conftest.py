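import numpy as np
import pytest

from bsapower import ExperimentalDesign, MutationEffects

# Mutant parameter sets used throughout: (mean effect %, SD ratio, s)
MUTANTS = {
    "YPW89": MutationEffects(10.45, 0.9467, 0.127),
    "YPW94": MutationEffects(7.21, 0.862, 0.130),
    "YPW102": MutationEffects(-3.25, 0.9251, 0.009),
}


@pytest.fixture
def mapping_design():
    """The mapping-experiment design: 10^7 segregants, 2% tails, 10+10
    generations, depth 75."""
    return ExperimentalDesign(
        population_size=10_000_000,
        cutoff_fraction=0.02,
        generations_pre=10,
        generations_post=10,
        depth=75,
        alpha=0.001,
        wild_type_cv=0.07572,
    )


@pytest.fixture
def survey_design():
    """The design-exploration baseline: 5% tails, depth 100."""
    return ExperimentalDesign(
        population_size=10_000_000,
        cutoff_fraction=0.05,
        generations_pre=10,
        generations_post=10,
        depth=100,
        alpha=0.001,
        wild_type_cv=0.07572,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
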