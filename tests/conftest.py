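import dataclasses

import numpy as np
import pytest

from paco2est.config import AlignmentConfig, GeneratorConfig
from paco2est.synth import generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-case cohort shared by read-only tests."""
    return generate_cohort(GeneratorConfig(n_cases=40, seed=11))


@pytest.fixture(scope="session")
def aligned_small(small_cohort):
    from paco2est.align import align_events
    return align_events(small_cohort, AlignmentConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def tiny_generator(**overrides) -> GeneratorConfig:
    base = GeneratorConfig(n_cases=8, seed=5,
                           case_duration_s=(3000.0, 4000.0),
                           abga_per_case=(1, 2))
    return dataclasses.replace(base, **overrides)
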