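"""Packaged childhood-asthma case fixtures.

The shipped case covers five negotiated issues -- treatment cost (0-8
thousand RMB), effectiveness (rank 1-10), side-effects and risk (fractions
of 0-1) and convenience (rank 1-10) -- with the doctor's and patient's
trapezoidal preferences, five candidate step-4 treatment plans, and three
issue-weight schemes for the recommendation step.
"""

from __future__ import annotations

from importlib import resources

from .io import load_plan_table, load_profile, load_weight_schemes
from .profiles import PreferenceProfile
from .recommend import TreatmentPlan, WeightScheme

__all__ = [
    "asthma_doctor_profile",
    "asthma_patient_profile",
    "asthma_plans",
    "asthma_weight_schemes",
    "fixture_path",
]


def fixture_path(name: str):
    """Filesystem path of a packaged fixture file (for the CLI and docs)."""
    return resources.files("fcan.data") / name


def asthma_doctor_profile() -> PreferenceProfile:
    return load_profile(fixture_path("asthma_doctor.yaml"))


def asthma_patient_profile() -> PreferenceProfile:
    return load_profile(fixture_path("asthma_patient.yaml"))


def asthma_plans() -> list[TreatmentPlan]:
    return load_plan_table(
        fixture_path("asthma_plans.yaml"), asthma_doctor_profile().issues
    )


def asthma_weight_schemes() -> list[WeightScheme]:
    return load_weight_schemes(fixture_path("asthma_weights.yaml"))
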