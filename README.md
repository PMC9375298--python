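# fcan — fuzzy constraint-directed agent negotiation for shared decision-making

Choosing a treatment together means a doctor and a patient reconciling
different priorities: the doctor may weigh effectiveness and side-effect
control, the patient cost and convenience.  `fcan` models this
preference-negotiation step of shared decision-making (SDM) as bilateral
multi-issue automated negotiation between a doctor agent (DA) and a patient
agent (PA), and then turns the agreed preference vector into a ranked list
of concrete treatment plans.

Each agent's preference on an issue is a trapezoidal fuzzy membership
function F_i (support = acceptable range, core = preferred range) with an
importance weight w_i; satisfaction with an offer S aggregates as

    Ψ(S) = Σ_i w_i · F_i(S_i)  ∈ [0, 1]        (aggregated satisfaction value, ASV).

Agents alternate offers under a round deadline.  Each round a declining
agent lowers its acceptance threshold ε by

    Δε = ( μ_ρ(ρ) ∧ μ_δ(δ) ∧ μ_σ(σ) ∧ μ_t(t) )^ω,     ε* = ε − Δε,

a fuzzy conjunction of its satisfaction ρ, tightness δ, the opponent's
responsiveness σ and time pressure t; the exponent ω selects the strategy
(collaborative ω < 1, win–win ω = 1, competitive ω > 1).  It then offers the
feasible solution (ASV in [ε*, ε]) that best balances its own membership
against similarity to the counteroffer, and accepts as soon as a
counteroffer satisfies Ψ(B) ≥ ε.  Agreements are ranked against treatment
plans by Φ(plan) = Σ_i w_i · s_i(S_i), where s_i is a trapezoid over the
plan's value bracket on issue i.

The package ships a complete childhood-asthma case (doctor and patient
profiles over cost, effectiveness, side-effects, risk and convenience, five
candidate plans, three weight schemes), a random-pair simulator for strategy
comparisons, and a time-driven concession tactic as baseline.

## Worked example

Negotiate the packaged asthma case and rank the plans:

```
$ fcan negotiate --pool-cap 20000 --out-dir out
outcome: agreement after 5 round(s)
final offer: [3.93, 8.0, 0.06, 0.04, 9.0]
ASV doctor:  0.6179
ASV patient: 0.5810
wrote out/transcript.csv and out/transcript.json
```

The agents agree in round 5 on a treatment profile costing 3.93 thousand
RMB with effectiveness rank 8, side-effect and risk levels of 6% and 4%,
and convenience rank 9; the doctor's and patient's satisfaction with it are
0.62 and 0.58.  `transcript.csv` holds the per-round concessions,
thresholds, feasible/prospective set sizes and offers.

The same machinery evaluates any agreed vector, e.g. the case's reference
agreement:

```
$ fcan recommend --agreement "3.79,9,0.07,0.07,9" --out-dir out
[doctor] ICS/LABA+THP > ICS/LABA > ICS/LABA+LTRA > ICS+LTRA > ICS+THP
[patient] ICS/LABA+THP > ICS/LABA > ICS+LTRA > ICS+THP > ICS/LABA+LTRA
[average] ICS/LABA+THP > ICS/LABA > ICS+LTRA > ICS+THP > ICS/LABA+LTRA
consensus across schemes: False
```

Under every weight scheme the top recommendation is the high-dose ICS/LABA
plus sustained-release theophylline plan (score 0.91–0.92): its brackets
contain the agreed cost, effectiveness and side-effect values.  The schemes
disagree further down — the doctor's effectiveness-heavy weights favour the
ICS/LABA+LTRA combination more than the patient's cost-heavy weights do —
so the consensus flag is False and the per-issue score breakdown in
`ranking.csv`/`ranking.json` shows which issues drive each placement.

Strategy comparison on random preference pairs:

```
$ fcan simulate --strategies all --issues 1,3,5 --reps 10 --seed 7 --out-dir out
```

writes a tidy per-run CSV and aggregates (mean rounds, mean combined ASV =
Ψ_DA + Ψ_PA ∈ [0, 2], failure counts).  Collaborative agents need the
fewest rounds and the time-driven baseline the most.

The same functionality is available as a library:

```python
import numpy as np
from fcan import EngineConfig, StrategyParams, datasets, run_negotiation

da = datasets.asthma_doctor_profile()
pa = datasets.asthma_patient_profile()
print(da.asv(np.array([3.79, 9, 0.07, 0.07, 9])))   # 0.5337
tr = run_negotiation(da, pa, EngineConfig(strategy=StrategyParams.preset("win_win")))
print(tr.outcome, tr.n_rounds)
```

See `docs/methods.md` for the model's assumptions, parameter defaults and
limitations.

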