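"""Issue schemas, trapezoidal fuzzy preferences and aggregated satisfaction.

A negotiating agent (doctor or patient) holds, for every issue under
negotiation (treatment cost, effectiveness, side-effects, ...), a
trapezoidal fuzzy membership function describing how satisfactory each
value of that issue is, together with an importance weight.  The weighted
sum of per-issue membership degrees is the *aggregated satisfaction value*
(ASV) of a candidate offer:

    asv(S) = sum_i  w_i * F_i(S_i),        sum_i w_i = 1,

so the ASV is itself a number in [0, 1].  The collection of issue
variables, memberships and weights forms the agent's fuzzy constraint
network; the set of grid offers with positive ASV is its *intension* --
everything the agent would entertain at all.

This module contains only the preference representation; the concession
and offer-generation machinery lives in :mod:`fcan.engine`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "IssueSchema",
    "TrapezoidalMembership",
    "PreferenceProfile",
    "ConstraintNetwork",
    "Offer",
    "membership_degree",
    "asv",
    "intension",
]

_WEIGHT_TOL = 1e-6
_GRID_TOL = 1e-9


class GridTooLargeError(ValueError):
    """Raised when an exhaustive grid enumeration would exceed the cap."""


@dataclass(frozen=True)
class IssueSchema:
    """Description of one negotiated issue.

    Parameters
    ----------
    name
        Identifier, e.g. ``"cost"``.
    units
        Free-text unit tag, e.g. ``"thousand-RMB"``, ``"rank"``,
        ``"fraction"``.
    domain_lo, domain_hi
        Admissible value range agreed by both parties.
    grid_step
        Discretization step; offers are snapped to this grid.
    value_kind
        ``"continuous"`` or ``"integer"``.
    goal
        ``"min"`` if smaller values are clinically preferable (cost,
        side-effects, risk), ``"max"`` otherwise.  Metadata only; the
        negotiation itself is driven by the membership functions.
    """

    name: str
    units: str
    domain_lo: float
    domain_hi: float
    grid_step: float
    value_kind: str = "continuous"
    goal: str = "min"

    def __post_init__(self) -> None:
        if not self.domain_lo < self.domain_hi:
            raise ValueError(f"{self.name}: domain_lo must be < domain_hi")
        if self.grid_step <= 0:
            raise ValueError(f"{self.name}: grid_step must be positive")
        n = (self.domain_hi - self.domain_lo) / self.grid_step
        if abs(n - round(n)) > 1e-6:
            raise ValueError(
                f"{self.name}: domain width must be an integer number of grid steps"
            )
        if self.value_kind not in ("continuous", "integer"):
            raise ValueError(f"{self.name}: unknown value_kind {self.value_kind!r}")
        if self.goal not in ("min", "max"):
            raise ValueError(f"{self.name}: goal must be 'min' or 'max'")

    @property
    def width(self) -> float:
        return self.domain_hi - self.domain_lo

    def grid(self, lo: float | None = None, hi: float | None = None) -> np.ndarray:
        """Grid points of this issue, optionally restricted to [lo, hi]."""
        lo = self.domain_lo if lo is None else max(lo, self.domain_lo)
        hi = self.domain_hi if hi is None else min(hi, self.domain_hi)
        start = np.ceil((lo - self.domain_lo) / self.grid_step - _GRID_TOL)
        stop = np.floor((hi - self.domain_lo) / self.grid_step + _GRID_TOL)
        idx = np.arange(start, stop + 1)
        g = self.domain_lo + idx * self.grid_step
        # kill representation noise such as 0.060000000000000005
        decimals = max(0, int(np.ceil(-np.log10(self.grid_step))) + 2)
        return np.round(g, decimals)

    def snap(self, x: float) -> float:
        """Snap a value onto the issue grid (nearest point, clipped)."""
        x = float(np.clip(x, self.domain_lo, self.domain_hi))
        k = round((x - self.domain_lo) / self.grid_step)
        v = self.domain_lo + k * self.grid_step
        decimals = max(0, int(np.ceil(-np.log10(self.grid_step))) + 2)
        v = float(np.round(v, decimals))
        return int(round(v)) if self.value_kind == "integer" else v


@dataclass(frozen=True)
class TrapezoidalMembership:
    """Trapezoidal membership function with support [a, d] and core [b, c].

    Degree is 0 outside ``[a, d]``, 1 on ``[b, c]`` and linear on the two
    shoulders.  Degenerate shoulders (``a == b`` or ``c == d``) yield step
    edges: the degree at such an edge is taken from the core side, i.e.
    ``degree(b) == 1`` always, while ``degree(a) == 0`` for ``a < b``.
    """

    support_lo: float
    core_lo: float
    core_hi: float
    support_hi: float

    def __post_init__(self) -> None:
        a, b, c, d = self.support_lo, self.core_lo, self.core_hi, self.support_hi
        if not (a <= b <= c <= d):
            raise ValueError(f"trapezoid requires a <= b <= c <= d, got {a, b, c, d}")

    def degree(self, x) -> np.ndarray | float:
        """Membership degree of ``x`` (scalar or array), clamped to [0, 1]."""
        a, b, c, d = self.support_lo, self.core_lo, self.core_hi, self.support_hi
        xx = np.asarray(x, dtype=float)
        out = np.zeros_like(xx)
        out = np.where((xx >= b) & (xx <= c), 1.0, out)
        if b > a:
            m = (xx >= a) & (xx < b)
            out = np.where(m, (xx - a) / (b - a), out)
        if d > c:
            m = (xx > c) & (xx <= d)
            out = np.where(m, (d - xx) / (d - c), out)
        out = np.clip(out, 0.0, 1.0)
        return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def membership_degree(m: TrapezoidalMembership, x) -> float | np.ndarray:
    """Functional alias for :meth:`TrapezoidalMembership.degree`."""
    return m.degree(x)


@dataclass(frozen=True)
class Offer:
    """A crisp value vector over the issue set, one value per issue."""

    values: tuple

    def __init__(self, values: Iterable[float]):
        object.__setattr__(self, "values", tuple(values))

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass
class PreferenceProfile:
    """An agent's full preference structure over the issue set.

    Holds one :class:`TrapezoidalMembership` and one nonnegative weight per
    issue, in the same order as ``issues``.  Weights must sum to 1 (within
    1e-6) unless ``normalize=True`` is passed, in which case they are
    rescaled.
    """

    agent_role: str
    issues: list[IssueSchema]
    memberships: list[TrapezoidalMembership]
    weights: np.ndarray
    normalize: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.issues)
        if len(self.memberships) != n or len(self.weights) != n:
            raise ValueError("issues, memberships and weights must have equal length")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        total = float(self.weights.sum())
        if abs(total - 1.0) > _WEIGHT_TOL:
            if self.normalize:
                if total == 0:
                    raise ValueError("cannot normalize all-zero weights")
                self.weights = self.weights / total
            else:
                raise ValueError(
                    f"weights sum to {total:.8f}, not 1 "
                    "(pass normalize=True to rescale)"
                )
        for sch, m in zip(self.issues, self.memberships):
            if m.support_lo < sch.domain_lo - _GRID_TOL or m.support_hi > sch.domain_hi + _GRID_TOL:
                raise ValueError(
                    f"{sch.name}: membership support [{m.support_lo}, {m.support_hi}] "
                    f"outside domain [{sch.domain_lo}, {sch.domain_hi}]"
                )

    @property
    def n_issues(self) -> int:
        return len(self.issues)

    def issue_index(self, name: str) -> int:
        for i, sch in enumerate(self.issues):
            if sch.name == name:
                return i
        raise KeyError(name)

    def degrees(self, offers: np.ndarray) -> np.ndarray:
        """Per-issue membership degrees of offers; shape (n_offers, n_issues)."""
        offers = np.atleast_2d(np.asarray(offers, dtype=float))
        if offers.shape[1] != self.n_issues:
            raise ValueError(
                f"offer has {offers.shape[1]} values, profile has {self.n_issues} issues"
            )
        cols = [m.degree(offers[:, i]) for i, m in enumerate(self.memberships)]
        return np.stack(cols, axis=1)

    def asv(self, offer) -> float | np.ndarray:
        """Aggregated satisfaction value of one offer or an array of offers."""
        if isinstance(offer, Offer):
            arr = offer.as_array()[None, :]
            return float(self.degrees(arr) @ self.weights)
        arr = np.asarray(offer, dtype=float)
        single = arr.ndim == 1
        vals = self.degrees(np.atleast_2d(arr)) @ self.weights
        return float(vals[0]) if single else vals

    def core_corner(self) -> np.ndarray:
        """The lexicographically smallest full-satisfaction offer.

        Every membership core corner has ASV exactly 1; the lower corner is
        the deterministic choice used as an agent's opening offer.
        """
        return np.array(
            [sch.snap(m.core_lo) for sch, m in zip(self.issues, self.memberships)],
            dtype=float,
        )


def asv(profile: PreferenceProfile, offer) -> float | np.ndarray:
    """Functional alias for :meth:`PreferenceProfile.asv`."""
    return profile.asv(offer)


@dataclass
class ConstraintNetwork:
    """An agent's fuzzy constraint network (universe, variables, constraints).

    The *intension* is the set of grid offers with strictly positive ASV;
    on small grids it can be enumerated exactly, which is the form used by
    the feasibility machinery and the brute-force oracles in the tests.
    """

    profile: PreferenceProfile

    @property
    def universe(self) -> list[IssueSchema]:
        return self.profile.issues

    def grid_size(self) -> int:
        return int(np.prod([len(s.grid()) for s in self.profile.issues]))

    def enumerate_grid(self, max_points: int = 250_000) -> np.ndarray:
        size = self.grid_size()
        if size > max_points:
            raise GridTooLargeError(
                f"grid has {size} points (> cap {max_points}); "
                "use a coarser grid_step or a sampled candidate pool"
            )
        grids = [s.grid() for s in self.profile.issues]
        mesh = np.meshgrid(*grids, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)

    def intension(self, max_points: int = 250_000) -> np.ndarray:
        """All grid offers with ASV > 0, shape (m, n_issues)."""
        pts = self.enumerate_grid(max_points)
        keep = self.profile.asv(pts) > 0
        return pts[keep]


def intension(profile: PreferenceProfile, max_points: int = 250_000) -> np.ndarray:
    """Grid offers of ``profile`` with positive aggregated satisfaction."""
    return ConstraintNetwork(profile).intension(max_points)
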