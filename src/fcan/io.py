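"""YAML readers/writers for profiles, plan tables, weight schemes and configs.

One structured-text dialect (YAML) is used for every input.  Loaders
validate eagerly and raise ``ValueError`` with the offending key so CLI
users get actionable messages.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .profiles import IssueSchema, PreferenceProfile, TrapezoidalMembership
from .recommend import TreatmentPlan, WeightScheme

__all__ = [
    "load_profile",
    "dump_profile",
    "load_plan_table",
    "load_weight_schemes",
]


def _require(mapping: dict, key: str, ctx: str):
    if key not in mapping:
        raise ValueError(f"{ctx}: missing required key {key!r}")
    return mapping[key]


def _parse_issue(doc: dict, ctx: str) -> tuple[IssueSchema, TrapezoidalMembership, float]:
    name = _require(doc, "name", ctx)
    ctx = f"{ctx}/{name}"
    lo, hi = _require(doc, "domain", ctx)
    a, d = _require(doc, "support", ctx)
    b, c = _require(doc, "core", ctx)
    schema = IssueSchema(
        name=name,
        units=doc.get("units", ""),
        domain_lo=float(lo),
        domain_hi=float(hi),
        grid_step=float(_require(doc, "step", ctx)),
        value_kind=doc.get("kind", "continuous"),
        goal=doc.get("goal", "min"),
    )
    member = TrapezoidalMembership(float(a), float(b), float(c), float(d))
    weight = float(_require(doc, "weight", ctx))
    return schema, member, weight


def load_profile(path: str | Path, normalize: bool = False) -> PreferenceProfile:
    """Load one agent's preference profile from a YAML document."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    role = _require(doc, "agent_role", str(path))
    issues_doc = _require(doc, "issues", str(path))
    schemas, members, weights = [], [], []
    for item in issues_doc:
        sch, mem, w = _parse_issue(item, str(path))
        schemas.append(sch)
        members.append(mem)
        weights.append(w)
    return PreferenceProfile(
        agent_role=role,
        issues=schemas,
        memberships=members,
        weights=np.asarray(weights),
        normalize=normalize,
    )


def dump_profile(profile: PreferenceProfile, path: str | Path) -> None:
    """Write a profile back to YAML (inverse of :func:`load_profile`)."""
    items: list[dict[str, Any]] = []
    for sch, mem, w in zip(profile.issues, profile.memberships, profile.weights):
        items.append(
            {
                "name": sch.name,
                "units": sch.units,
                "domain": [sch.domain_lo, sch.domain_hi],
                "step": sch.grid_step,
                "kind": sch.value_kind,
                "goal": sch.goal,
                "support": [mem.support_lo, mem.support_hi],
                "core": [mem.core_lo, mem.core_hi],
                "weight": float(w),
            }
        )
    doc = {"agent_role": profile.agent_role, "issues": items}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _convert_units(lo: float, hi: float, from_units: str, to_units: str, ctx: str):
    if from_units == to_units:
        return lo, hi
    if from_units == "percent" and to_units == "fraction":
        return lo / 100.0, hi / 100.0
    if from_units == "fraction" and to_units == "percent":
        return lo * 100.0, hi * 100.0
    raise ValueError(f"{ctx}: cannot convert units {from_units!r} -> {to_units!r}")


def load_plan_table(
    path: str | Path, issues: list[IssueSchema]
) -> list[TreatmentPlan]:
    """Load a treatment-plan table and normalize units onto the issue scales.

    The table declares the units each column is written in (e.g. the
    side-effects column in ``percent``); values are converted onto the
    corresponding :class:`IssueSchema` scale (e.g. ``fraction``) on load.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    cols = _require(doc, "issues", str(path))
    units = doc.get("units", {})
    by_name = {s.name: s for s in issues}
    unknown = [c for c in cols if c not in by_name]
    if unknown:
        raise ValueError(f"{path}: plan table issues {unknown} not in the schema")
    plans = []
    for item in _require(doc, "plans", str(path)):
        name = _require(item, "name", str(path))
        ranges = {}
        for col in cols:
            lo, hi = _require(_require(item, "ranges", name), col, name)
            lo, hi = _convert_units(
                float(lo), float(hi), units.get(col, by_name[col].units),
                by_name[col].units, f"{name}/{col}",
            )
            ranges[col] = (lo, hi)
        plans.append(
            TreatmentPlan(name=name, ranges=ranges, note=item.get("note", ""))
        )
    return plans


def load_weight_schemes(path: str | Path) -> list[WeightScheme]:
    """Load named issue-weight schemes (rows must each sum to 1)."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    out = []
    for item in _require(doc, "schemes", str(path)):
        name = _require(item, "name", str(path))
        weights = {k: float(v) for k, v in _require(item, "weights", name).items()}
        out.append(WeightScheme(name=name, weights=weights))
    return out
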