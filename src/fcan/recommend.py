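"""Ranking candidate treatment plans against a negotiated agreement.

A treatment plan is characterized by a value *range* on each negotiated
issue (a cost bracket, an expected effectiveness band, ...).  The agreed
preference vector is matched against each plan with a per-issue fuzzy
similarity and aggregated with an issue-weight scheme:

    score(plan) = sum_i  w_i * s_i(agreement_i),

where ``s_i`` is a trapezoid whose core is the plan's range on issue *i*
and whose shoulders extend ``spread`` times the issue's domain width on
each side.  A value inside the plan range scores 1; similarity then decays
linearly to 0 at the shoulder edge.  An exponential kernel over the
scaled distance to the range is available as an alternative.

Scores are computed under one or more weight schemes (doctor's weights,
patient's weights, their average); the plans are ranked per scheme and a
consensus flag records whether every scheme produced the same order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import IssueSchema

__all__ = [
    "TreatmentPlan",
    "WeightScheme",
    "RecommendationResult",
    "issue_similarity",
    "score_plan",
    "rank_plans",
]

DEFAULT_SPREAD = 0.25
_WEIGHT_TOL = 1e-6


@dataclass(frozen=True)
class TreatmentPlan:
    """A named plan with a (lo, hi) value range per issue."""

    name: str
    ranges: dict  # issue name -> (lo, hi), on the issue's own scale
    note: str = ""

    def __post_init__(self) -> None:
        for issue, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"{self.name}/{issue}: range lo > hi")


@dataclass(frozen=True)
class WeightScheme:
    """Named issue weights summing to 1."""

    name: str
    weights: dict  # issue name -> weight

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"scheme {self.name!r}: weights sum to {total}, not 1")


@dataclass
class RecommendationResult:
    """Per-plan scores, rankings per scheme, and the consensus flag."""

    scores: pd.DataFrame          # index: plan name, columns: scheme name
    breakdown: pd.DataFrame       # tidy: plan, scheme, issue, similarity, weighted
    rankings: dict = field(default_factory=dict)  # scheme -> list of plan names
    consensus: bool = False

    def ranking(self, scheme: str) -> list:
        return self.rankings[scheme]


def issue_similarity(
    value: float,
    value_range: tuple,
    issue: IssueSchema,
    spread: float = DEFAULT_SPREAD,
    kernel: str = "trapezoid",
) -> float:
    """Similarity in [0, 1] between one agreed value and a plan's range.

    ``kernel="trapezoid"`` (default): 1 inside the range, decaying linearly
    to 0 over ``spread * issue.width`` on each side.
    ``kernel="exponential"``: exp(-d / spread) where d is the distance to
    the range scaled by the domain width.
    """
    if spread < 0:
        raise ValueError("spread must be >= 0")
    lo, hi = value_range
    d = max(lo - value, value - hi, 0.0)
    if d == 0.0:
        return 1.0
    if kernel == "trapezoid":
        shoulder = spread * issue.width
        if shoulder == 0:
            return 0.0
        return float(max(0.0, 1.0 - d / shoulder))
    if kernel == "exponential":
        if spread == 0:
            return 0.0
        return float(np.exp(-(d / issue.width) / spread))
    raise ValueError(f"unknown kernel {kernel!r}")


def score_plan(
    agreement,
    plan: TreatmentPlan,
    scheme: WeightScheme,
    issues: list[IssueSchema],
    spread: float = DEFAULT_SPREAD,
    kernel: str = "trapezoid",
) -> float:
    """Weighted similarity score of one plan against the agreement vector."""
    values = np.asarray(
        agreement.as_array() if hasattr(agreement, "as_array") else agreement,
        dtype=float,
    )
    if len(values) != len(issues):
        raise ValueError("agreement length does not match the issue set")
    total = 0.0
    for i, sch in enumerate(issues):
        if sch.name not in plan.ranges:
            raise ValueError(f"plan {plan.name!r} has no range for issue {sch.name!r}")
        w = scheme.weights.get(sch.name)
        if w is None:
            raise ValueError(f"scheme {scheme.name!r} has no weight for {sch.name!r}")
        total += w * issue_similarity(values[i], plan.ranges[sch.name], sch, spread, kernel)
    return float(total)


def rank_plans(
    agreement,
    plans: list[TreatmentPlan],
    schemes: list[WeightScheme],
    issues: list[IssueSchema],
    spread: float = DEFAULT_SPREAD,
    kernel: str = "trapezoid",
) -> RecommendationResult:
    """Score and rank plans under each weight scheme.

    Rankings are descending by score; exact ties break alphabetically by
    plan name.  ``consensus`` is True when every scheme yields the same
    order.
    """
    if not plans:
        raise ValueError("at least one treatment plan is required")
    values = np.asarray(
        agreement.as_array() if hasattr(agreement, "as_array") else agreement,
        dtype=float,
    )
    rows = []
    for plan in plans:
        for scheme in schemes:
            for i, sch in enumerate(issues):
                s = issue_similarity(values[i], plan.ranges[sch.name], sch, spread, kernel)
                rows.append(
                    {
                        "plan": plan.name,
                        "scheme": scheme.name,
                        "issue": sch.name,
                        "similarity": s,
                        "weighted": scheme.weights[sch.name] * s,
                    }
                )
    breakdown = pd.DataFrame(rows)
    scores = (
        breakdown.groupby(["plan", "scheme"])["weighted"].sum().unstack("scheme")
    )
    rankings = {}
    for scheme in schemes:
        col = scores[scheme.name]
        order = sorted(col.index, key=lambda p: (-col[p], p))
        rankings[scheme.name] = order
    orders = list(rankings.values())
    consensus = all(o == orders[0] for o in orders[1:])
    return RecommendationResult(
        scores=scores, breakdown=breakdown, rankings=rankings, consensus=consensus
    )
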