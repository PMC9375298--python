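import numpy as np
import pytest

from fcan import (
    IssueSchema,
    PreferenceProfile,
    TrapezoidalMembership,
    datasets,
)

# the final agreed preference vector of the packaged asthma case
ASTHMA_AGREEMENT = np.array([3.79, 9, 0.07, 0.07, 9])


@pytest.fixture(scope="session")
def da_profile():
    return datasets.asthma_doctor_profile()


@pytest.fixture(scope="session")
def pa_profile():
    return datasets.asthma_patient_profile()


@pytest.fixture(scope="session")
def asthma_plans():
    return datasets.asthma_plans()


@pytest.fixture(scope="session")
def asthma_schemes():
    return datasets.asthma_weight_schemes()


def unit_issue(name="x", step=0.1, goal="min"):
    return IssueSchema(
        name=name, units="normalized", domain_lo=0.0, domain_hi=1.0,
        grid_step=step, value_kind="continuous", goal=goal,
    )


def make_profile(trapezoids, weights=None, step=0.1, role="doctor"):
    """Small helper: profile over unit-domain issues from (a,b,c,d) tuples."""
    issues = [unit_issue(f"x{i}", step=step) for i in range(len(trapezoids))]
    members = [TrapezoidalMembership(*t) for t in trapezoids]
    if weights is None:
        weights = np.full(len(trapezoids), 1.0 / len(trapezoids))
    return PreferenceProfile(
        agent_role=role, issues=issues, memberships=members,
        weights=np.asarray(weights, dtype=float),
    )


def brute_force_asv_band(profile, offers, lo, hi, tol=1e-9):
    """Reference band filter: offers whose ASV lies in [lo, hi]."""
    keep = []
    for row in np.atleast_2d(offers):
        v = profile.asv(row)
        if lo - tol <= v <= hi + tol:
            keep.append(row)
    return np.array(keep).reshape(-1, np.atleast_2d(offers).shape[1])
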