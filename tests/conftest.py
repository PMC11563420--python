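import numpy as np
import pytest

import crcscreen as cs


@pytest.fixture(scope="session")
def loaded():
    """Packaged defaults: (ModelParameters, CostSchedule, UtilitySchedule)."""
    return cs.load_parameters()


@pytest.fixture(scope="session")
def params(loaded):
    return loaded[0]


@pytest.fixture(scope="session")
def costs(loaded):
    return loaded[1]


@pytest.fixture(scope="session")
def utilities(loaded):
    return loaded[2]


@pytest.fixture()
def rng():
    return np.random.default_rng(20190301)


def make_cohort(n, age=60, state=None, diagnosed=False, dx_stage=None,
                track=None, years_since_dx=0, years_since_surv=0):
    """Hand-built cohort in a specific starting condition."""
    from crcscreen._states import State, Track
    from crcscreen.cohort import Cohort

    c = Cohort.of_ages(np.full(n, age, dtype=np.int64))
    if state is not None:
        c.state[:] = int(state)
    if diagnosed:
        c.diagnosed[:] = True
        c.dx_stage[:] = int(dx_stage if dx_stage is not None else state)
        c.years_since_dx[:] = years_since_dx
        c.track[:] = int(Track.NATURAL_HISTORY)
    if track is not None:
        c.track[:] = int(track)
    c.years_since_surveillance[:] = years_since_surv
    return c
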