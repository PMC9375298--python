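"""Alternating-offers message protocol binding two negotiation engines.

The initiator (doctor agent by default) opens with *Ask* carrying its
initial offer; the responder either *Agree*s (provisional acceptance,
confirmed by the opponent's *Accept*) or replies *Tell* with a
counteroffer.  From round 2 on, each agent that declines a counteroffer
concedes, rebuilds its feasible and prospective sets and sends a new
offer.  *Abort* ends the negotiation when a threshold reaches its
reservation level or a feasible set empties; passing the round deadline
fails the negotiation outright.

A "round" is one Ask/Tell exchange pair; the opening Ask is round 1.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import (
    AgentState,
    CandidatePool,
    DesireFunctions,
    EngineConfig,
    Outcome,
    StateVector,
    concession_step,
    feasible_set,
    generate_offer,
    internal_state,
    prospective_set,
    responsive_state,
    time_pressure,
)
from .profiles import PreferenceProfile

__all__ = [
    "MessageKind",
    "Message",
    "RoundRecord",
    "NegotiationTranscript",
    "run_negotiation",
    "validate_sequence",
]


class MessageKind(str, enum.Enum):
    ASK = "Ask"
    TELL = "Tell"
    ACCEPT = "Accept"
    REJECT = "Reject"
    AGREE = "Agree"
    ABORT = "Abort"


_CARRIES_OFFER = {MessageKind.ASK, MessageKind.TELL, MessageKind.AGREE, MessageKind.ACCEPT}

# state machine: predecessor kind -> allowed successor kinds
_TRANSITIONS = {
    None: {MessageKind.ASK},
    MessageKind.ASK: {MessageKind.TELL, MessageKind.AGREE, MessageKind.ABORT, MessageKind.REJECT},
    MessageKind.TELL: {MessageKind.ASK, MessageKind.AGREE, MessageKind.ABORT, MessageKind.REJECT},
    MessageKind.AGREE: {MessageKind.ACCEPT, MessageKind.ABORT},
    MessageKind.REJECT: {MessageKind.ABORT},
    MessageKind.ACCEPT: set(),
    MessageKind.ABORT: set(),
}


@dataclass(frozen=True)
class Message:
    kind: MessageKind
    sender: str
    receiver: str
    payload: tuple | None
    round: int

    def __post_init__(self):
        if self.kind in _CARRIES_OFFER and self.payload is None:
            raise ValueError(f"{self.kind.value} message requires an offer payload")
        if self.kind not in _CARRIES_OFFER and self.payload is not None:
            raise ValueError(f"{self.kind.value} message must not carry an offer")


def validate_sequence(messages) -> bool:
    """True iff the message kinds form a path of the protocol state machine."""
    prev = None
    for msg in messages:
        kind = msg.kind if isinstance(msg, Message) else MessageKind(msg)
        if kind not in _TRANSITIONS[prev]:
            return False
        prev = kind
    return True


@dataclass
class RoundRecord:
    round: int
    actor: str
    kind: str
    offer: tuple | None
    delta_eps: float
    epsilon_new: float
    n_feasible: int
    n_prospective: int
    own_asv: float


@dataclass
class NegotiationTranscript:
    """Round-by-round record of one negotiation and its outcome."""

    messages: list = field(default_factory=list)
    rounds: list = field(default_factory=list)
    outcome: str = ""
    final_offer: tuple | None = None
    final_asv_da: float | None = None
    final_asv_pa: float | None = None
    n_rounds: int = 0
    diagnostic: str = ""
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rounds])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_json(self, path: str | Path) -> None:
        doc = {
            "metadata": self.metadata,
            "outcome": self.outcome,
            "n_rounds": self.n_rounds,
            "final_offer": self.final_offer,
            "final_asv_da": self.final_asv_da,
            "final_asv_pa": self.final_asv_pa,
            "diagnostic": self.diagnostic,
            "messages": [
                {
                    "kind": m.kind.value,
                    "sender": m.sender,
                    "receiver": m.receiver,
                    "payload": m.payload,
                    "round": m.round,
                }
                for m in self.messages
            ],
            "rounds": [vars(r) for r in self.rounds],
        }
        Path(path).write_text(json.dumps(doc, indent=2))


def _as_payload(offer: np.ndarray) -> tuple:
    return tuple(float(v) for v in offer)


def _check_same_schema(da: PreferenceProfile, pa: PreferenceProfile) -> None:
    if [s.name for s in da.issues] != [s.name for s in pa.issues]:
        raise ValueError("both profiles must share one issue schema")
    for sa, sb in zip(da.issues, pa.issues):
        if (sa.domain_lo, sa.domain_hi, sa.grid_step) != (
            sb.domain_lo,
            sb.domain_hi,
            sb.grid_step,
        ):
            raise ValueError(f"issue {sa.name!r}: domain/grid differ between profiles")


def run_negotiation(
    da_profile: PreferenceProfile,
    pa_profile: PreferenceProfile,
    config: EngineConfig | None = None,
    initiator: str = "DA",
    pools: dict | None = None,
) -> NegotiationTranscript:
    """Drive a full negotiation between the doctor and patient agents.

    ``pools`` may pre-supply a :class:`CandidatePool` per agent id
    ("DA"/"PA") to avoid rebuilding them across repeated runs.
    """
    config = config or EngineConfig()
    _check_same_schema(da_profile, pa_profile)
    if initiator not in ("DA", "PA"):
        raise ValueError("initiator must be 'DA' or 'PA'")

    rng = np.random.default_rng(config.seed)
    states: dict[str, AgentState] = {}
    for name, profile in (("DA", da_profile), ("PA", pa_profile)):
        pool = (pools or {}).get(name) or CandidatePool.support_box(
            profile, cap=config.pool_cap, rng=rng
        )
        states[name] = AgentState(
            profile=profile,
            params=config.strategy,
            pool=pool,
            reservation=config.reservation,
        )

    other = {"DA": "PA", "PA": "DA"}
    order = [initiator, other[initiator]]
    transcript = NegotiationTranscript(
        metadata={
            "strategy": config.strategy.strategy_name,
            "omega": config.strategy.omega,
            "omega1": config.strategy.omega1,
            "omega2": config.strategy.omega2,
            "r_max": config.r_max,
            "reservation": config.reservation,
            "seed": config.seed,
            "initiator": initiator,
            "time_driven": config.time_driven,
        }
    )

    def finish(outcome: str, offer: np.ndarray | None = None, diagnostic: str = ""):
        transcript.outcome = outcome
        transcript.diagnostic = diagnostic
        if offer is not None:
            transcript.final_offer = _as_payload(offer)
            transcript.final_asv_da = float(da_profile.asv(offer))
            transcript.final_asv_pa = float(pa_profile.asv(offer))
        return transcript

    def send(kind: MessageKind, sender: str, offer: np.ndarray | None, r: int):
        transcript.messages.append(
            Message(
                kind=kind,
                sender=sender,
                receiver=other[sender],
                payload=None if offer is None else _as_payload(offer),
                round=r,
            )
        )

    def record(r, actor, kind, offer, deps, eps, nP, nS, own):
        transcript.rounds.append(
            RoundRecord(
                round=r,
                actor=actor,
                kind=kind,
                offer=None if offer is None else _as_payload(offer),
                delta_eps=deps,
                epsilon_new=eps,
                n_feasible=nP,
                n_prospective=nS,
                own_asv=own,
            )
        )

    def accept(acceptor: str, offer: np.ndarray, r: int) -> NegotiationTranscript:
        send(MessageKind.AGREE, acceptor, offer, r)
        send(MessageKind.ACCEPT, other[acceptor], offer, r)
        record(
            r, acceptor, "Agree", offer, 0.0, states[acceptor].epsilon, 0, 0,
            float(states[acceptor].profile.asv(offer)),
        )
        transcript.n_rounds = r
        return finish("agreement", offer)

    opp_offer: np.ndarray | None = None
    prev_signature = None

    for r in range(1, config.r_max + 1):
        for actor in order:
            st = states[actor]
            # 1. evaluate the standing counteroffer against the current threshold
            if opp_offer is not None:
                if float(st.profile.asv(opp_offer)) >= st.epsilon - 1e-12:
                    return accept(actor, opp_offer, r)
            if r == 1:
                # opening round: each side states its aspiration, no concession
                off = st.profile.core_corner()
                st.last_offer = off
                st.first_own_offer = off
                if opp_offer is not None:
                    st.first_counteroffer = opp_offer
                    st.last_counteroffer = opp_offer
                kind = MessageKind.ASK if actor == initiator else MessageKind.TELL
                send(kind, actor, off, r)
                record(r, actor, kind.value, off, 0.0, st.epsilon, len(st.pool), 1,
                       float(st.profile.asv(off)))
                opp_offer = off
                continue

            # 2. concession
            if st.first_counteroffer is None:
                st.first_counteroffer = opp_offer
            st.last_counteroffer = opp_offer
            if config.time_driven:
                # boulware-style late concession: exponent > 1 on the round ratio
                t_b = config.strategy.k_time + (1 - config.strategy.k_time) * (
                    r / config.r_max
                ) ** config.beta_time
                eps_new = min(st.epsilon, 1.0 - t_b)
                delta_eps = st.epsilon - eps_new
            else:
                sigma, _ = responsive_state(
                    st.first_own_offer, st.first_counteroffer,
                    st.last_offer, st.last_counteroffer, st.schema,
                )
                rho, delta = internal_state(st)
                t = time_pressure(
                    r, config.r_max, config.strategy.k_time, config.strategy.beta
                )
                sv = StateVector(sigma=sigma, rho=rho, delta=delta, t=t)
                delta_eps, eps_new = concession_step(
                    st, sv, config.desires, config.tnorm
                )
            if eps_new <= st.reservation + 1e-12:
                send(MessageKind.ABORT, actor, None, r)
                record(r, actor, "Abort", None, delta_eps, eps_new, 0, 0, float("nan"))
                transcript.n_rounds = r
                return finish(Outcome.FAIL_THRESHOLD.value)

            # 3. feasible and prospective sets, offer generation
            P = feasible_set(st.pool, st.epsilon, eps_new)
            if len(P) == 0:
                send(MessageKind.ABORT, actor, None, r)
                record(r, actor, "Abort", None, delta_eps, eps_new, 0, 0, float("nan"))
                transcript.n_rounds = r
                return finish(Outcome.FAIL_EMPTY.value)
            S_star = prospective_set(st, P, opp_offer, config.w2_form)
            off = generate_offer(S_star, opp_offer, config.strategy.k_sim, st.schema)
            st.epsilon = eps_new
            st.last_offer = off
            st.rho = float(st.profile.asv(off))
            st.feasible = P
            st.prospective = S_star
            kind = MessageKind.ASK if actor == initiator else MessageKind.TELL
            send(kind, actor, off, r)
            record(r, actor, kind.value, off, delta_eps, eps_new, len(P), len(S_star),
                   st.rho)
            opp_offer = off

        signature = (
            tuple(states["DA"].last_offer), tuple(states["PA"].last_offer),
            round(states["DA"].epsilon, 12), round(states["PA"].epsilon, 12),
        )
        if signature == prev_signature:
            send(MessageKind.ABORT, order[0], None, r)
            transcript.n_rounds = r
            return finish(
                "fail_deadlock",
                diagnostic="identical offers repeated with no threshold movement",
            )
        prev_signature = signature

    transcript.n_rounds = config.r_max
    return finish(Outcome.FAIL_DEADLINE.value)
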