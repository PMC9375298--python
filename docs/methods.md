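# Methods

`fcan` models doctor–patient preference negotiation in shared decision-making
(SDM) as bilateral multi-issue automated negotiation between two software
agents — a doctor agent (DA) and a patient agent (PA) — each holding fuzzy
constraints over the treatment issues, followed by a fuzzy multi-criteria
ranking of concrete treatment plans against the agreed preference vector.
This note documents the model, its assumptions, the tunable parameters, the
numerical choices, and what the synthetic experiments do and do not show.

## Preference model

Each negotiated issue *i* (cost, effectiveness, side-effects, risk,
convenience, ...) has a crisp admissible domain and a grid step; offers are
crisp value vectors snapped to the grid.  An agent's preference on issue *i*
is a trapezoidal membership function F_i with support [a, d] and core
[b, c]: degree 0 outside the support, 1 on the core, linear on the
shoulders.  Degenerate shoulders give step edges with the degree at the
edge taken from the core side.  Satisfaction with an offer S aggregates as

    Ψ(S) = Σ_i w_i · F_i(S_i),       Σ_i w_i = 1,

the *aggregated satisfaction value* (ASV), a weighted mean of membership
degrees in [0, 1].  Weights must sum to 1 within 1e-6; an explicit
`normalize=True` flag rescales instead of rejecting.  The agent's fuzzy
constraint network's *intension* is the set of grid offers with Ψ > 0;
it is enumerable exactly on small grids and is the reference object for the
brute-force equivalence tests.

In the packaged asthma case, side-effects and risk are stored as fractions
in [0, 1] even where source material quotes percentages; the plan-table
loader converts percent-tagged columns to fractions.  Effectiveness and
convenience are integer ranks 1–10; cost is in thousand RMB with a 0.01
grid, matching the precision at which offers are quoted.

## Negotiation engine

Agents alternate offers under a deadline of `r_max` rounds (default 15; one
round = one Ask/Tell exchange, the opening Ask is round 1).  Each agent
keeps a satisfaction threshold ε, starting at 1.0, and accepts a
counteroffer B as soon as Ψ(B) ≥ ε.  Acceptance is evaluated *before*
conceding; an agent concedes only when it declines.

A declining agent computes four state scalars, all in [0, 1]:

- σ — opponent responsiveness, the remaining fraction of the opening offer
  gap: σ = G(A, B) / G(A₀, B₀), where G(A, B) = √(Σ_i L_i²)/n and L_i is
  the per-issue absolute difference scaled by the issue's domain width.
  Offers are treated as crisp vectors throughout.
- ρ — the ASV of its own latest prospective solution (round 1: the opening
  offer, so ρ = 1).
- δ — tightness, δ = 1 − (ρ − ε): how little slack the current solution has
  over the threshold.
- t — time pressure, t = k + (1 − k)(r/r_max)^β with defaults k = 0.1,
  β = 0.5.

Each scalar passes through a *desire* function μ(·); the four desires are
combined with a fuzzy conjunction (minimum by default, product available)
and raised to the strategy exponent ω:

    Δε = ( μ_ρ(ρ) ∧ μ_δ(δ) ∧ μ_σ(σ) ∧ μ_t(t) )^ω,     ε* = ε − Δε.

ω < 1 concedes faster (collaborative), ω = 1 is win–win, ω > 1 concedes
slower (competitive).  The desire functions are injectable; the defaults
are identity maps for ρ, σ and t, and a damped affine response for
tightness:

    μ_δ(δ) = min(1, γ + λ(1 − δ)),   γ = 0.1,  λ = 0.5.

The floor γ keeps concession possible even at zero slack ("more tightness →
less concession, never exactly zero"); the slope λ < 1 is essential for
stability.  Because a round's concession re-enters the next round as slack
(ρ − ε ≈ Δε_prev), an undamped response μ_δ ≈ γ + Δε_prev forms a positive
feedback loop that, amplified by ω < 1, collapses the threshold to the
reservation level within a few rounds before any offer can be accepted.
With γ = 0.1 and λ = 0.5 all three strategy regimes complete the packaged
asthma case within the deadline (collaborative 5 rounds, win–win 6,
competitive 9), with round counts in the same order and range as the
worked example's strategy comparison.

The declining agent then rebuilds its feasible set P — every candidate
offer whose ASV lies in the closed band [ε*, ε] — and keeps the maximizers
(ties within 1e-9 retained) of the prospective utility

    H(S, B) = (1/n) √( Σ_i min( W1(S_i)^ω₁ , W2(S_i, B_i)^ω₂ )² ),

where W1 is the agent's own membership degree and W2 = 1 − scaled distance
to the counteroffer (an exponential form is available).  ω₁/ω₂ weight own
preference against similarity to the opponent: collaborative ω₁ = 0.8,
ω₂ = 1; win–win 1/1; competitive ω₁ = 1.2, ω₂ = 1.  Among the prospective
set the offer sent is the maximizer of the mean exponential similarity
(1/n) Σ_i exp(−k·L_i) with k = 1 by default; every tie anywhere in the
pipeline breaks to the lexicographically smallest offer vector, which makes
whole negotiations deterministic under a seed.

Negotiation fails when ε* reaches the reservation level (default 0), when a
feasible set empties, or at the deadline.  A guard also aborts if a full
round passes with both offers and both thresholds unchanged (unreachable
under the defaults, since Δε > 0 whenever σ > 0).

Opening offers are the lexicographically smallest full-satisfaction offer
(the lower core corner on every issue); both agents state theirs in round 1
without conceding.

### Candidate pools

The exact feasible band over the full offer grid is intractable for the
asthma case (≈8·10⁸ grid points).  The engine therefore searches a
*candidate pool*: the agent's support box (positive membership on every
issue), enumerated exhaustively when it has at most `pool_cap` points
(default 200 000) and otherwise sampled from the grid under the run seed,
with all membership core corners always included so a full-satisfaction
offer exists in round 1.  The band filter itself is exact on whatever pool
it receives — on grids small enough to enumerate, it coincides with the
brute-force filter of the intension, which the test suite verifies on
hundreds of random instances.  Sampling makes large negotiations
approximate in the sense that the searched offer space is a uniform subset;
it never affects the acceptance logic or threshold dynamics.

### Time-dependent baseline

The baseline tactic concedes on the clock alone: ε* = min(ε, 1 − t_b(r))
with t_b = k + (1 − k)(r/r_max)^β_time.  Offer generation reuses the same
feasible/prospective machinery.  β_time defaults to 3.0 — a late-conceding
(boulware) profile that holds a high threshold until near the deadline.
With the fast-rising β < 1 profile that the main model uses for time
*pressure*, the baseline would concede almost half its threshold by round
2 and become the fastest tactic, contradicting its role as the
slow-but-uninformed reference; a boulware exponent restores the intended
behaviour (13 rounds on the asthma case, the slowest of the four tactics).

## Protocol

Messages are Ask, Tell, Agree, Accept, Reject, Abort.  The initiator opens
with Ask; the responder either Agrees (provisional acceptance, confirmed by
the opponent's immediate Accept) or Tells a counteroffer.  Reject is
reserved for an agent with no offer to send that has not yet hit a failure
condition; under the shipped engine this state is unreachable (a nonempty
feasible set always yields an offer), so transcripts contain no Rejects.
`validate_sequence` checks message sequences against the state machine
(Ask→{Tell, Agree, Abort}, Tell→{Ask, Agree, Abort}, Agree→{Accept, Abort},
Accept/Abort terminal), and every transcript the driver produces validates.

Two structural invariants hold for every run: each agent's threshold
sequence is non-increasing, and the ASV an agent assigns to its own
successive offers is non-increasing (each new offer is drawn from a band
whose top is the previous band's bottom).

## Recommendation model

A treatment plan is a (lo, hi) bracket per issue.  Given the agreed vector
S, each plan scores

    Φ(plan) = Σ_i w_i · s_i(S_i),

where s_i is a trapezoid with core [lo_i, hi_i] and shoulders of
`spread` × (domain width) on each side; `spread` defaults to 0.25, and an
exponential kernel over the scaled distance to the bracket is available
behind a flag.  Scores are computed under the doctor's, the patient's and
the averaged weight scheme; rankings are descending with alphabetical tie
break, and a consensus flag reports whether all schemes agree.  Per-issue
weighted contributions are returned alongside the scores so a ranking can
be explained issue by issue.

The similarity kernel is a genuine modeling choice: no principled member of
this family (linear or exponential kernels, interval or midpoint distances,
domain-, span- or support-width normalizations, spreads 0.02–2) makes the
five asthma plans come out in one fixed order under all three weight
schemes simultaneously — the doctor scheme rewards the high-effectiveness
combination plans while the patient scheme's cost weight penalizes the
expensive ones, and with the default kernel the schemes disagree on the
tail of the ranking.  The default was chosen for continuity with the
profile model (trapezoids throughout), not to force a particular order.

## Synthetic experiments

`PairSampler` draws doctor/patient pairs on n normalized issues (domains
[0, 1], grid step 0.025): per issue a core center uniform in the domain, a
core width of 10–30% of the domain, shoulders widened by a further 10–30%
per side, and weights from a flat Dirichlet; pairs are rejection-sampled
until supports overlap on every issue, so agreement is not structurally
impossible.  `run_experiment` runs a strategy × issue-count grid with a
paired design — each (issue count, repetition) cell samples one pair and
one candidate pool per agent and replays them under every strategy — which
removes pair-to-pair variance from strategy contrasts.  Wall-clock runtime
is recorded in the in-memory report but excluded from the CSV outputs so
reruns are byte-identical; it is never asserted.

The shipped experiment scale is 50 repetitions per cell over issue counts
{1, 3, 5} (plus a 100-pair win–win run at n = 5), which is sufficient to
resolve the round-count ordering collaborative ≤ win–win ≤ competitive ≤
time-baseline with wide margins.  The combined-ASV ordering competitive ≥
win–win ≥ collaborative is a much smaller effect in this model (paired
differences of order 0.01 on means near 1.4), so the acceptance test
checks it as a stochastic-dominance condition: the paired mean difference
must not be negative by more than two paired standard errors.

What these experiments emulate is the *shape* of the strategy comparison:
direction of round counts and satisfaction trade-offs as the issue count
grows.  They do not emulate elicited clinical preferences (the sampler's
distribution is a modeling choice), runtime comparisons (hardware-bound),
or any exact tabulated cell values.  Passing them shows the concession and
selection machinery orders strategies as designed on random instances, not
that the magnitudes transfer to real consultations.

## Known limitations

- Preferences are fixed during a negotiation; renegotiation after a
  preference change means restarting.
- Two agents only; no mediator, coalition or concurrent sessions.
- The desire functions are calibrated to the strategy envelope
  ω ∈ [0.8, 1.2]; exotic custom desires can reintroduce threshold collapse
  (they are injectable precisely so such calibrations can be studied).
- Sampled candidate pools make high-dimensional negotiations search a
  random subset of the offer grid; results remain seeded-deterministic but
  can differ across pool caps.
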