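import pytest

import armsml
from armsml._solvers import warm_up
from armsml.types import BalancedSubsample


@pytest.fixture(scope="session", autouse=True)
def _jit_warm_up():
    # compile the numba solvers once so individual tests are not timed
    # against JIT compilation
    warm_up()


@pytest.fixture(scope="session")
def smri_cohort():
    """A cohort shaped like the imaging sub-sample: 23 T / 76 NT over
    three protocols."""
    return armsml.generate_cohort(23, 76, (14 / 23, 3 / 23, 6 / 23), seed=101)


@pytest.fixture(scope="session")
def balanced(smri_cohort):
    return armsml.balance_subsample(smri_cohort, seed=7)


def balanced_pair_cohort(n_pairs: int, seed: int):
    """A 50/50 cohort plus the trivial all-in balanced subsample."""
    cohort = armsml.generate_cohort(n_pairs, n_pairs, seed=seed)
    ss = BalancedSubsample(cohort.ids_of("T"), cohort.ids_of("NT"),
                           attempt_count=1, age_p=1.0, sex_p=1.0, seed=seed)
    return cohort, ss


@pytest.fixture(scope="session")
def labels_of():
    def _get(cohort):
        return cohort.phenotypes.set_index("subject_id")["transition"]
    return _get
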