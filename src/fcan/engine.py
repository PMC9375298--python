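"""Concession, feasibility, offer generation and termination for one agent.

Each negotiation round an agent that has just received a counteroffer B
runs four steps:

1. *Concession.*  Four state scalars in [0, 1] are read off the table:
   sigma, the opponent's responsive state (how much of the initial
   offer gap remains); rho, the agent's satisfaction with its latest
   prospective solution; delta, the "tightness" ``1 - (rho - epsilon)``;
   and t, the time pressure.  Each is mapped through a *desire* function,
   the desires are combined with a fuzzy conjunction (minimum by default)
   and raised to the strategy exponent omega:

       delta_eps = (mu_rho ^ mu_delta ^ mu_sigma ^ mu_t) ** omega,
       epsilon_new = epsilon - delta_eps.

   omega < 1 concedes faster (collaborative), omega = 1 is win-win,
   omega > 1 concedes slower (competitive).

2. *Feasible set.*  All candidate offers whose ASV lies in the closed
   band [epsilon_new, epsilon].

3. *Prospective set and offer.*  Among feasible offers, keep the
   maximizers of the utility

       H(S, B) = (1/n) * sqrt( sum_i min(W1(S_i)**w1, W2(S_i,B_i)**w2)^2 ),

   where W1 is the agent's own membership degree and W2 a similarity to
   the counteroffer; then send the prospective offer most similar to B
   under a mean exponential kernel.

4. *Termination.*  Accept when the counteroffer's ASV reaches the
   threshold; fail when the threshold hits the reservation level, the
   feasible set empties, or the deadline passes.

Candidate offers live in a :class:`CandidatePool`: the agent's support box
(positive membership on every issue) enumerated exhaustively when small
enough, otherwise grid-sampled under the run seed with the membership core
corners always included.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .profiles import IssueSchema, PreferenceProfile

__all__ = [
    "Outcome",
    "StateVector",
    "StrategyParams",
    "DesireFunctions",
    "EngineConfig",
    "CandidatePool",
    "AgentState",
    "offer_distance",
    "responsive_state",
    "internal_state",
    "time_pressure",
    "concession_step",
    "feasible_set",
    "prospective_set",
    "generate_offer",
    "check_termination",
]

TIE_TOL = 1e-9


class DeadlineExceededError(RuntimeError):
    pass


class Outcome(str, enum.Enum):
    CONTINUE = "continue"
    AGREE = "agree"
    FAIL_THRESHOLD = "fail_threshold"
    FAIL_EMPTY = "fail_empty"
    FAIL_DEADLINE = "fail_deadline"


@dataclass(frozen=True)
class StateVector:
    """The four concession drivers, each clamped to [0, 1]."""

    sigma: float
    rho: float
    delta: float
    t: float

    def __post_init__(self):
        for name in ("sigma", "rho", "delta", "t"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class StrategyParams:
    """Concession exponent and prospective-utility exponents.

    ``omega`` shapes the concession size; ``omega1``/``omega2`` weight own
    preference vs similarity to the opponent when selecting prospective
    solutions.  Presets:

    ==============  =====  ======  ======
    strategy        omega  omega1  omega2
    ==============  =====  ======  ======
    collaborative    0.8     0.8     1.0
    win_win          1.0     1.0     1.0
    competitive      1.2     1.2     1.0
    ==============  =====  ======  ======
    """

    omega: float
    omega1: float
    omega2: float
    k_time: float = 0.1
    beta: float = 0.5
    k_sim: float = 1.0
    strategy_name: str = "custom"

    def __post_init__(self):
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie in (0, 1)")
        if not 0 <= self.k_time <= 1:
            raise ValueError("k_time must lie in [0, 1]")
        if self.k_sim <= 0:
            raise ValueError("k_sim must be positive")
        name = self.strategy_name
        if name == "collaborative":
            ok = self.omega1 <= 1 and self.omega2 <= 1 and self.omega1 < self.omega2 and self.omega < 1
        elif name == "win_win":
            ok = self.omega1 == self.omega2 <= 1 and self.omega == 1
        elif name == "competitive":
            ok = self.omega1 >= 1 and self.omega2 >= 1 and self.omega1 > self.omega2 and self.omega > 1
        else:
            ok = True
        if not ok:
            raise ValueError(
                f"exponents (omega={self.omega}, omega1={self.omega1}, "
                f"omega2={self.omega2}) violate the {name} regime"
            )

    @classmethod
    def preset(cls, name: str, **overrides) -> "StrategyParams":
        presets = {
            "collaborative": dict(omega=0.8, omega1=0.8, omega2=1.0),
            "win_win": dict(omega=1.0, omega1=1.0, omega2=1.0),
            "competitive": dict(omega=1.2, omega1=1.2, omega2=1.0),
        }
        if name not in presets:
            raise ValueError(f"unknown strategy {name!r}; choose from {sorted(presets)}")
        kw = presets[name] | overrides
        return cls(strategy_name=name, **kw)


# Default desire maps.  The tightness desire is deliberately damped:
# mu_delta = gamma + lam * (1 - delta) keeps "more tightness -> less
# concession" with a floor gamma > 0, while the slope lam < 1 prevents the
# previous round's concession (which re-enters as slack rho - epsilon) from
# escalating round over round.
DELTA_FLOOR = 0.1
DELTA_SLOPE = 0.5


def _default_delta_desire(delta: float) -> float:
    return min(1.0, DELTA_FLOOR + DELTA_SLOPE * (1.0 - delta))


@dataclass(frozen=True)
class DesireFunctions:
    """Injectable maps [0,1] -> [0,1] turning state scalars into desires."""

    rho: Callable[[float], float] = lambda r: r
    sigma: Callable[[float], float] = lambda s: s
    t: Callable[[float], float] = lambda t: t
    delta: Callable[[float], float] = _default_delta_desire


@dataclass
class EngineConfig:
    """Run-wide engine settings shared by both agents."""

    strategy: StrategyParams = field(
        default_factory=lambda: StrategyParams.preset("collaborative")
    )
    r_max: int = 15
    reservation: float = 0.0
    pool_cap: int = 200_000
    seed: int = 0
    tnorm: str = "min"              # or "product"
    w2_form: str = "linear"         # or "exponential"
    desires: DesireFunctions = field(default_factory=DesireFunctions)
    time_driven: bool = False       # pure time-dependent threshold baseline
    beta_time: float = 3.0          # late-conceding exponent for the baseline

    def __post_init__(self):
        if self.r_max < 1:
            raise ValueError("r_max must be >= 1")
        if self.tnorm not in ("min", "product"):
            raise ValueError("tnorm must be 'min' or 'product'")
        if self.w2_form not in ("linear", "exponential"):
            raise ValueError("w2_form must be 'linear' or 'exponential'")
        if self.beta_time <= 0:
            raise ValueError("beta_time must be positive")


# ---------------------------------------------------------------------------
# candidate pools


@dataclass
class CandidatePool:
    """Grid offers an agent can propose, with their ASVs precomputed."""

    offers: np.ndarray     # (m, n_issues)
    asvs: np.ndarray       # (m,)
    exhaustive: bool       # True when the full support box is enumerated

    def __len__(self) -> int:
        return len(self.offers)

    @classmethod
    def from_offers(cls, profile: PreferenceProfile, offers: np.ndarray,
                    exhaustive: bool = True) -> "CandidatePool":
        offers = np.atleast_2d(np.asarray(offers, dtype=float))
        return cls(offers=offers, asvs=np.asarray(profile.asv(offers)),
                   exhaustive=exhaustive)

    @classmethod
    def support_box(
        cls,
        profile: PreferenceProfile,
        cap: int = 200_000,
        rng: np.random.Generator | None = None,
    ) -> "CandidatePool":
        """Build the pool from the profile's support box.

        Exhaustive product grid when its size is <= ``cap``; otherwise
        ``cap`` grid points are drawn uniformly (per-issue independent)
        under ``rng``.  The 2^n membership core corners are always added,
        so a full-satisfaction offer is available in round 1.
        """
        grids = [
            sch.grid(mem.support_lo, mem.support_hi)
            for sch, mem in zip(profile.issues, profile.memberships)
        ]
        sizes = [len(g) for g in grids]
        if any(s == 0 for s in sizes):
            raise ValueError("a membership support contains no grid point")
        total = float(np.prod([float(s) for s in sizes]))
        if total <= cap:
            mesh = np.meshgrid(*grids, indexing="ij")
            offers = np.stack([m.ravel() for m in mesh], axis=1)
            exhaustive = True
        else:
            rng = np.random.default_rng(0) if rng is None else rng
            idx = np.stack([rng.integers(0, s, size=cap) for s in sizes], axis=1)
            offers = np.stack([grids[i][idx[:, i]] for i in range(len(grids))], axis=1)
            offers = np.unique(offers, axis=0)
            exhaustive = False
        corners = np.array(
            list(
                itertools.product(
                    *[
                        {sch.snap(mem.core_lo), sch.snap(mem.core_hi)}
                        for sch, mem in zip(profile.issues, profile.memberships)
                    ]
                )
            ),
            dtype=float,
        )
        offers = np.unique(np.vstack([offers, corners]), axis=0)
        return cls.from_offers(profile, offers, exhaustive=exhaustive)


# ---------------------------------------------------------------------------
# agent state


@dataclass
class AgentState:
    """Mutable negotiation state of one agent."""

    profile: PreferenceProfile
    params: StrategyParams
    pool: CandidatePool
    epsilon: float = 1.0
    reservation: float = 0.0
    first_own_offer: np.ndarray | None = None    # A0
    first_counteroffer: np.ndarray | None = None  # B0
    last_offer: np.ndarray | None = None          # A
    last_counteroffer: np.ndarray | None = None   # B
    rho: float = 1.0   # ASV of the latest prospective solution
    feasible: np.ndarray | None = None
    prospective: np.ndarray | None = None

    @property
    def schema(self) -> list[IssueSchema]:
        return self.profile.issues


# ---------------------------------------------------------------------------
# operations


def _widths(schema: Sequence[IssueSchema]) -> np.ndarray:
    return np.array([s.width for s in schema], dtype=float)


def offer_distance(a, b, schema: Sequence[IssueSchema]) -> float:
    """Scaled offer distance G(A, B) = sqrt(sum_i L_i^2) / n.

    Each per-issue distance L_i is |a_i - b_i| scaled by the issue's domain
    width, so G is dimensionless and G <= 1/sqrt(n).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(schema)
    if a.shape != (n,) or b.shape != (n,):
        raise ValueError("offers do not match the issue schema")
    L = np.abs(a - b) / _widths(schema)
    return float(np.sqrt((L ** 2).sum()) / n)


def responsive_state(A0, B0, A, B, schema: Sequence[IssueSchema]) -> tuple[float, bool]:
    """Opponent responsiveness sigma = G(A,B)/G(A0,B0), clamped to [0, 1].

    Returns ``(sigma, immediate_agreement)``; the flag is True when the
    very first offers already coincide (G(A0, B0) = 0).
    """
    g0 = offer_distance(A0, B0, schema)
    if g0 == 0.0:
        return 0.0, True
    g = offer_distance(A, B, schema)
    return float(np.clip(g / g0, 0.0, 1.0)), False


def internal_state(state: AgentState) -> tuple[float, float]:
    """(rho, delta): satisfaction with the latest prospective solution and
    the tightness delta = 1 - (rho - epsilon), both clamped to [0, 1]."""
    rho = float(np.clip(state.rho, 0.0, 1.0))
    delta = float(np.clip(1.0 - (rho - state.epsilon), 0.0, 1.0))
    return rho, delta


def time_pressure(r_now: int, r_max: int, k_time: float, beta: float) -> float:
    """t = k + (1 - k) (r_now / r_max)^beta; t(0) = k, t(r_max) = 1."""
    if r_max < 1:
        raise ValueError("r_max must be >= 1")
    if r_now < 0:
        raise ValueError("r_now must be >= 0")
    if r_now > r_max:
        raise DeadlineExceededError(f"round {r_now} exceeds deadline {r_max}")
    return float(k_time + (1.0 - k_time) * (r_now / r_max) ** beta)


def concession_step(
    state: AgentState,
    sv: StateVector,
    desires: DesireFunctions | None = None,
    tnorm: str = "min",
) -> tuple[float, float]:
    """Concession delta_eps >= 0 and the updated threshold epsilon_new."""
    desires = desires or DesireFunctions()
    mus = (
        float(np.clip(desires.rho(sv.rho), 0, 1)),
        float(np.clip(desires.delta(sv.delta), 0, 1)),
        float(np.clip(desires.sigma(sv.sigma), 0, 1)),
        float(np.clip(desires.t(sv.t), 0, 1)),
    )
    agg = min(mus) if tnorm == "min" else float(np.prod(mus))
    delta_eps = agg ** state.params.omega
    return delta_eps, state.epsilon - delta_eps


def feasible_set(pool: CandidatePool, epsilon: float, epsilon_new: float) -> np.ndarray:
    """Offers whose ASV lies in the closed band [epsilon_new, epsilon]."""
    if epsilon_new > epsilon + TIE_TOL:
        raise ValueError("epsilon_new must not exceed epsilon")
    mask = (pool.asvs >= epsilon_new - TIE_TOL) & (pool.asvs <= epsilon + TIE_TOL)
    return pool.offers[mask]


def _w2(P: np.ndarray, B: np.ndarray, schema, form: str, k_sim: float) -> np.ndarray:
    scaled = np.abs(P - B) / _widths(schema)
    if form == "linear":
        return np.clip(1.0 - scaled, 0.0, 1.0)
    return np.exp(-k_sim * scaled)


def prospective_set(
    state: AgentState,
    P: np.ndarray,
    B: np.ndarray | None,
    w2_form: str = "linear",
    tie_tol: float = TIE_TOL,
) -> np.ndarray:
    """Subset of the feasible set maximizing H(S, B), ties retained.

    With no counteroffer yet (opening round of the initiator) the
    maximal-ASV offers are returned instead.
    """
    P = np.atleast_2d(P)
    if len(P) == 0:
        raise ValueError("prospective_set requires a nonempty feasible set")
    if B is None:
        a = np.asarray(state.profile.asv(P))
        return P[a >= a.max() - tie_tol]
    n = state.profile.n_issues
    W1 = state.profile.degrees(P)
    W2 = _w2(P, np.asarray(B, dtype=float), state.schema, w2_form, state.params.k_sim)
    inner = np.minimum(W1 ** state.params.omega1, W2 ** state.params.omega2)
    H = np.sqrt((inner ** 2).sum(axis=1)) / n
    return P[H >= H.max() - tie_tol]


def _lex_smallest(offers: np.ndarray) -> np.ndarray:
    order = np.lexsort(offers[:, ::-1].T)
    return offers[order[0]]


def generate_offer(
    S_star: np.ndarray,
    B: np.ndarray | None,
    k_sim: float,
    schema: Sequence[IssueSchema],
) -> np.ndarray:
    """The prospective offer most similar to B (mean exponential kernel).

    Similarity uses per-issue distances scaled by domain width, matching
    :func:`offer_distance`.  Ties -- including the k_sim -> 0 limit where
    every similarity approaches 1 -- break to the lexicographically
    smallest offer vector.
    """
    S_star = np.atleast_2d(S_star)
    if len(S_star) == 0:
        raise ValueError("generate_offer requires a nonempty prospective set")
    if B is None:
        return _lex_smallest(S_star)
    scaled = np.abs(S_star - np.asarray(B, dtype=float)) / _widths(schema)
    sim = np.exp(-k_sim * scaled).mean(axis=1)
    best = S_star[sim >= sim.max() - TIE_TOL]
    return _lex_smallest(best)


def check_termination(
    state: AgentState,
    B: np.ndarray | None,
    P: np.ndarray | None,
    r_now: int,
    r_max: int,
) -> Outcome:
    """Outcome of the current round from this agent's point of view."""
    if r_now > r_max:
        return Outcome.FAIL_DEADLINE
    if B is not None and float(state.profile.asv(np.asarray(B))) >= state.epsilon - TIE_TOL:
        return Outcome.AGREE
    if state.epsilon <= state.reservation + TIE_TOL:
        return Outcome.FAIL_THRESHOLD
    if P is not None and len(P) == 0:
        return Outcome.FAIL_EMPTY
    return Outcome.CONTINUE
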