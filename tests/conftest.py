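import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from lcmem.config import BehaviorSpec, CohortConfig, CouplingSpec
from lcmem.synthetic_data import gen_stage_dataset

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Six subjects, short stages — fast enough for pipeline round-trips."""
    return CohortConfig(n_subjects=6, series_length=300, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    coupling = {
        stage: CouplingSpec(band_center=0.2, band_width=0.02, target_msc=0.8, target_phase=np.pi / 2)
        for stage in small_cohort.stages
    }
    return gen_stage_dataset(
        small_cohort,
        coupling_by_stage=coupling,
        behavior=BehaviorSpec(),
        saa_effects={"consolidation": 60.0},
    )
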