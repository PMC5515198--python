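import numpy as np
import pytest

from metachain import Cohort, MetEvent, Pathway, PatientRecord


def pw(*steps, patient_id=None):
    """Build a Pathway from site names / iterables of site names."""
    out = []
    for s in steps:
        out.append(frozenset({s}) if isinstance(s, str) else frozenset(s))
    return Pathway(steps=tuple(out), patient_id=patient_id)


@pytest.fixture
def make_patient():
    def _make(pid="p1", er="positive", her2="negative", vital="alive",
              followup=12.0, events=()):
        return PatientRecord(
            patient_id=pid,
            er_status=er,
            her2_status=her2,
            vital_status=vital,
            followup_years=followup,
            events=tuple(MetEvent(site=s, time=t) for t, s in events),
        )
    return _make


@pytest.fixture
def small_cohort(make_patient):
    """Five patients spanning both eligibility branches and both vital states."""
    return Cohort(patients=(
        make_patient("a", followup=12.0, events=[(2.0, "bone"), (5.0, "liver")]),
        make_patient("b", followup=6.0),  # alive, short follow-up: ineligible
        make_patient("c", vital="deceased", followup=4.0,
                     events=[(2.0, "bone"), (3.1, "liver")]),
        make_patient("d", er="negative", her2="negative", vital="deceased",
                     followup=11.0, events=[(1.0, "lung_pleura")]),
        make_patient("e", her2="positive", followup=15.0,
                     events=[(3.0, "bone"), (3.01, "ln_distant")]),
    ))


def random_transition_matrix(seed, n_extra_sites=4):
    """Seeded random row-stochastic matrix with absorbing deceased state."""
    from metachain import TransitionMatrix

    rng = np.random.default_rng(seed)
    sites = ("breast",) + tuple(f"s{i}" for i in range(n_extra_sites)) + ("deceased",)
    n = len(sites)
    probs = rng.dirichlet(np.ones(n), size=n)
    probs[-1] = 0.0
    probs[-1, -1] = 1.0
    return TransitionMatrix(sites=sites, probs=probs)
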