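import pytest

from gaitprog.preprocess import preprocess
from gaitprog.simulate import CohortConfig, generate_cohort


def small_config(**overrides) -> CohortConfig:
    """Reduced cohort for fast unit tests; same structure as the default."""
    base = dict(
        n_participants=24,
        n_features=24,
        n_progressing=8,
        n_collinear_blocks=4,
        seed=11,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_preprocessed(small_cohort):
    cohort, scores, truth = small_cohort
    pre, log = preprocess(cohort, scores)
    return pre, truth


@pytest.fixture(scope="session")
def paper_scale():
    """One default-sized cohort, preprocessed; shared by the slower tests."""
    cohort, scores, truth = generate_cohort(CohortConfig(seed=5))
    pre, _ = preprocess(cohort, scores)
    return pre, truth
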