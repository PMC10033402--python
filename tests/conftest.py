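import pytest

from stagewise import AttainedDesign, TrialOutcome, TwoStageDesign
from stagewise.fixtures import (
    ipi_nivo_ct_cohort,
    ipi_nivo_ct_outcome,
    nivo_ct_cohort,
    nivo_ct_outcome,
)


@pytest.fixture(scope="session")
def trial_design() -> TwoStageDesign:
    """The minimax design under study: 2/15 futility, 5/21 efficacy,
    p0=0.15 vs p1=0.40 at one-sided alpha=beta=0.10."""
    return TwoStageDesign(r1=2, n1=15, r=5, n=21, p0=0.15, p1=0.40, alpha=0.10, beta=0.10)


@pytest.fixture(scope="session")
def attained() -> AttainedDesign:
    """Attained design: both arms over-enrolled stage 2 to 7 subjects."""
    return AttainedDesign(r1=2, n1=15, n2=7)


@pytest.fixture(scope="session")
def outcome_s7(attained) -> TrialOutcome:
    return nivo_ct_outcome()


@pytest.fixture(scope="session")
def outcome_s11(attained) -> TrialOutcome:
    return ipi_nivo_ct_outcome()


@pytest.fixture(scope="session")
def cohort_c():
    return nivo_ct_cohort()


@pytest.fixture(scope="session")
def cohort_d():
    return ipi_nivo_ct_cohort()
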