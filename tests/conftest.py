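import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mmnbs import (ClinicalSpec, CohortSpec, EffectSpec, FCSpec,
                   generate_cohort)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def small_spec(seed: int = 0, **overrides) -> CohortSpec:
    """A fast, fully in-range cohort spec for unit tests (12 regions)."""
    base = dict(
        n_patients=8,
        n_controls=7,
        n_regions=12,
        effects=(
            EffectSpec("GMV", (8, 9, 10, 11), -2.0),
            EffectSpec("FA", (10, 11), -1.5),
        ),
        fc=FCSpec(series_length=60, base_correlation=0.1,
                  planted_edges=((2, 10, 0.5), (3, 10, 0.5))),
        clinical=ClinicalSpec(target_correlations=(("FA", 10, -0.5),)),
        seed=seed,
    )
    base.update(overrides)
    return CohortSpec(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_spec(seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
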