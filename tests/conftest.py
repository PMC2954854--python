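import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg", force=True)

from regretdca import Cohort


@pytest.fixture
def toy_cohort() -> Cohort:
    """Four-patient cohort with one of each confusion cell at Pt = 0.5."""
    return Cohort.from_records([(0.9, 1), (0.6, 0), (0.3, 1), (0.1, 0)])


def random_cohort(rng: np.random.Generator, n: int) -> Cohort:
    risks = rng.random(n)
    outcomes = rng.integers(0, 2, size=n)
    if outcomes.sum() == 0:
        outcomes[0] = 1  # keep prevalence positive so no strategy degenerates
    return Cohort(risks, outcomes)
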