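"""Randomized negotiation experiments: strategy and baseline comparisons.

Random doctor/patient preference pairs are drawn on a normalized issue
space (each issue on [0, 1]): per issue, a core center uniform in the
domain, a core width of 10-30% of the domain, support shoulders widened by
a further 10-30% per side, and weights from a flat Dirichlet draw.  Pairs
are rejection-sampled until the two supports overlap on every issue, so a
mutually satisfying offer exists at least in principle.  The experiment
grid runs each sampled pair under every requested strategy (paired design,
which removes pair-to-pair variance from strategy contrasts) and records
the agreement round count and the combined satisfaction

    combined ASV = ASV_doctor(agreement) + ASV_patient(agreement)  in [0, 2].

Failed negotiations are recorded separately and excluded from ASV means.
The pure time-dependent concession tactic ("time" strategy), whose
threshold is driven only by the round clock, serves as the baseline.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import AgentState, CandidatePool, EngineConfig, StrategyParams
from .profiles import IssueSchema, PreferenceProfile, TrapezoidalMembership
from .protocol import run_negotiation

__all__ = [
    "PairSampler",
    "sample_pair",
    "ExperimentReport",
    "run_experiment",
    "time_baseline",
    "STRATEGIES",
]

STRATEGIES = ("collaborative", "win_win", "competitive", "time")

_SIM_STEP = 0.025  # grid step of the normalized simulation issues


def _make_config(strategy: str, seed: int, r_max: int, pool_cap: int) -> EngineConfig:
    if strategy == "time":
        return EngineConfig(
            strategy=StrategyParams.preset("win_win"),
            time_driven=True,
            seed=seed,
            r_max=r_max,
            pool_cap=pool_cap,
        )
    return EngineConfig(
        strategy=StrategyParams.preset(strategy),
        seed=seed,
        r_max=r_max,
        pool_cap=pool_cap,
    )


def time_baseline(
    state: AgentState, r_now: int, r_max: int,
    k_time: float = 0.1, beta_time: float = 3.0,
) -> float:
    """Threshold of the time-dependent baseline at round ``r_now``.

    epsilon* = min(epsilon, 1 - t) with t = k + (1-k)(r_now/r_max)^beta_time;
    concession is driven purely by the clock.  beta_time > 1 postpones
    concession toward the deadline (boulware behaviour); beta_time = 1 with
    k = 0 decays the threshold linearly.
    """
    if r_max < 1:
        raise ValueError("r_max must be >= 1")
    if not 0 <= r_now <= r_max:
        raise ValueError("r_now must lie in [0, r_max]")
    t = k_time + (1.0 - k_time) * (r_now / r_max) ** beta_time
    return float(min(state.epsilon, 1.0 - t))


@dataclass
class PairSampler:
    """Reproducible random doctor/patient preference-pair generator."""

    n_issues: int
    seed: int = 0
    core_width: tuple = (0.1, 0.3)     # fraction of the domain
    shoulder_width: tuple = (0.1, 0.3)  # widening per side, fraction of domain

    def __post_init__(self):
        if not 1 <= self.n_issues <= 9:
            raise ValueError("n_issues must lie in 1..9")
        self._schemas = [
            IssueSchema(
                name=f"issue_{i + 1}",
                units="normalized",
                domain_lo=0.0,
                domain_hi=1.0,
                grid_step=_SIM_STEP,
                value_kind="continuous",
                goal="min",
            )
            for i in range(self.n_issues)
        ]

    @property
    def schemas(self) -> list[IssueSchema]:
        return self._schemas

    def _profile(self, role: str, rng: np.random.Generator) -> PreferenceProfile:
        members = []
        for _ in range(self.n_issues):
            w = rng.uniform(*self.core_width)
            center = rng.uniform(0.0, 1.0)
            b = float(np.clip(center - w / 2, 0.0, 1.0))
            c = float(np.clip(center + w / 2, 0.0, 1.0))
            a = float(np.clip(b - rng.uniform(*self.shoulder_width), 0.0, 1.0))
            d = float(np.clip(c + rng.uniform(*self.shoulder_width), 0.0, 1.0))
            members.append(TrapezoidalMembership(a, b, c, d))
        weights = rng.dirichlet(np.ones(self.n_issues))
        return PreferenceProfile(
            agent_role=role,
            issues=self._schemas,
            memberships=members,
            weights=weights,
        )

    def pair(self, rng: np.random.Generator | None = None):
        """One (doctor, patient) pair with overlapping supports on every issue."""
        rng = np.random.default_rng(self.seed) if rng is None else rng
        while True:
            da = self._profile("doctor", rng)
            pa = self._profile("patient", rng)
            ok = all(
                min(ma.support_hi, mb.support_hi) > max(ma.support_lo, mb.support_lo)
                for ma, mb in zip(da.memberships, pa.memberships)
            )
            if ok:
                return da, pa


def sample_pair(n: int, seed: int = 0):
    """Convenience wrapper: one reproducible pair over ``n`` issues."""
    return PairSampler(n_issues=n, seed=seed).pair()


@dataclass
class ExperimentReport:
    """Tidy per-run results plus aggregation helpers."""

    runs: pd.DataFrame
    config: dict = field(default_factory=dict)

    def aggregate(self, by=("strategy",)) -> pd.DataFrame:
        """Mean rounds/combined ASV per group; ASV means over agreements only."""
        df = self.runs
        ok = df[df["outcome"] == "agreement"]
        g_ok = ok.groupby(list(by))
        out = pd.DataFrame(
            {
                "mean_rounds": g_ok["rounds"].mean(),
                "sem_rounds": g_ok["rounds"].sem(),
                "mean_combined_asv": g_ok["combined_asv"].mean(),
                "sem_combined_asv": g_ok["combined_asv"].sem(),
                "n_agreements": g_ok.size(),
            }
        )
        out["n_failures"] = (
            df[df["outcome"] != "agreement"].groupby(list(by)).size()
        )
        out["n_failures"] = out["n_failures"].fillna(0).astype(int)
        return out.reset_index()

    def write_csv(self, runs_path, aggregate_path=None) -> None:
        # runtime is wall-clock and hence non-deterministic; it stays in the
        # in-memory frame but is excluded from files so reruns are identical
        self.runs.drop(columns=["runtime_s"]).to_csv(runs_path, index=False)
        if aggregate_path is not None:
            self.aggregate(by=("strategy", "n_issues")).to_csv(
                aggregate_path, index=False
            )


def _child_seed(seed: int, n: int, rep: int) -> int:
    return (seed * 1_000_003 + n * 10_007 + rep * 101) % (2**31 - 1)


def run_experiment(
    strategies=STRATEGIES,
    issue_counts=(1, 3, 5, 7, 9),
    reps: int = 50,
    seed: int = 0,
    r_max: int = 15,
    pool_cap: int = 20_000,
) -> ExperimentReport:
    """Run the strategy x issue-count grid and collect per-run results.

    Each (issue count, repetition) cell samples one preference pair and one
    candidate pool per agent, then replays them under every strategy, so
    strategy contrasts are paired.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    unknown = set(strategies) - set(STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies {sorted(unknown)}")
    rows = []
    for n in issue_counts:
        for rep in range(reps):
            cseed = _child_seed(seed, n, rep)
            rng = np.random.default_rng(cseed)
            da, pa = PairSampler(n_issues=n, seed=cseed).pair(rng)
            pools = {
                "DA": CandidatePool.support_box(da, cap=pool_cap, rng=rng),
                "PA": CandidatePool.support_box(pa, cap=pool_cap, rng=rng),
            }
            for strategy in strategies:
                config = _make_config(strategy, cseed, r_max, pool_cap)
                t0 = time.perf_counter()
                tr = run_negotiation(da, pa, config, pools=pools)
                elapsed = time.perf_counter() - t0
                rows.append(
                    {
                        "strategy": strategy,
                        "n_issues": n,
                        "rep": rep,
                        "seed": cseed,
                        "outcome": tr.outcome,
                        "rounds": tr.n_rounds,
                        "asv_da": tr.final_asv_da,
                        "asv_pa": tr.final_asv_pa,
                        "combined_asv": (
                            None
                            if tr.final_asv_da is None
                            else tr.final_asv_da + tr.final_asv_pa
                        ),
                        "runtime_s": elapsed,
                    }
                )
    runs = pd.DataFrame(rows)
    return ExperimentReport(
        runs=runs,
        config={
            "strategies": list(strategies),
            "issue_counts": list(issue_counts),
            "reps": reps,
            "seed": seed,
            "r_max": r_max,
            "pool_cap": pool_cap,
        },
    )
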