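import pytest

from diaflow import CohortConfig, default_cutoffs, simulate_cohort
from diaflow.core import ModalityMeasurements, SubjectRecord


@pytest.fixture(scope="session")
def echo_cutoffs():
    return default_cutoffs("echo")


@pytest.fixture(scope="session")
def flow_cutoffs():
    return default_cutoffs("flow4d")


@pytest.fixture(scope="session")
def default_cohort():
    """One 94-subject cohort at the default study conditions."""
    return simulate_cohort(CohortConfig(), seed=11)


@pytest.fixture(scope="session")
def large_cohort():
    """Default conditions scaled 10x, for estimator-recovery checks."""
    cfg = CohortConfig(n_per_grade=(510, 90, 130, 130, 80))
    return simulate_cohort(cfg, seed=11)


def make_record(subject_id="S1", disease=False, echo=None, flow=None,
                true_grade=None):
    """A valid record with normal-range defaults, overridable per field."""
    echo_kw = dict(ef=62.0, lavi=30.0, e_peak=80.0, a_peak=72.0,
                   e_prime_septal=10.0, e_prime_lateral=13.0, tr_peak=2.0)
    flow_kw = dict(ef=67.0, lavi=43.0, e_peak=80.0, a_peak=72.0,
                   e_prime_septal=10.0, e_prime_lateral=13.0, t_vortex=0.0)
    echo_kw.update(echo or {})
    flow_kw.update(flow or {})
    return SubjectRecord(subject_id=subject_id,
                         echo=ModalityMeasurements(**echo_kw),
                         flow4d=ModalityMeasurements(**flow_kw),
                         myocardial_disease=disease, true_grade=true_grade)
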