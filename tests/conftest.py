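import numpy as np
import pytest

import strokeburden as sb
from strokeburden import cohort as cohort_mod


@pytest.fixture(scope="session")
def params():
    return sb.load_parameters()


@pytest.fixture(scope="session")
def life_table(params):
    mortality = sb.calibrate(dict(params.le_targets), max_age=params.max_age)
    return sb.build_life_table(mortality)


@pytest.fixture(scope="session")
def full_cohort(params):
    return cohort_mod.sample_cohort(params.cohort, params.initial_distribution, seed=1234)


@pytest.fixture(scope="session")
def zero_hazard_table(params):
    """A life table with no mortality below the terminal age."""
    return sb.build_life_table(sb.MortalityParams(0.0, 0.0, 0.1, params.max_age))


def uniform_cohort(n, age, mrs, spec):
    """A hand-built cohort: everyone the same age and entry state."""
    return cohort_mod.Cohort(
        ids=np.arange(n),
        age_at_entry=np.full(n, float(age)),
        sex=np.zeros(n, dtype=np.int8),
        initial_mrs=np.full(n, mrs, dtype=np.int8),
        stroke_type=np.zeros(n, dtype=np.int8),
        group_index=np.zeros(n, dtype=np.int8),
        spec=spec,
        seed=0,
    )
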