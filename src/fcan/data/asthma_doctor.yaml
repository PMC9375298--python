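# Doctor-agent preferences for the childhood-asthma case (grade-4 severity,
# 8-year-old): trapezoid support = [minimum, maximum] preference value,
# core = the preferred value range; weights sum to 1.
agent_role: doctor
issues:
  - name: cost
    units: thousand-RMB
    domain: [0, 8]
    step: 0.01
    kind: continuous
    goal: min
    support: [3.5, 8]
    core: [4, 8]
    weight: 0.15
  - name: effectiveness
    units: rank
    domain: [1, 10]
    step: 1
    kind: integer
    goal: max
    support: [5, 10]
    core: [7, 8]
    weight: 0.3
  - name: side_effects
    units: fraction
    domain: [0, 1]
    step: 0.01
    kind: continuous
    goal: min
    support: [0.01, 0.25]
    core: [0.1, 0.15]
    weight: 0.25
  - name: risk
    units: fraction
    domain: [0, 1]
    step: 0.01
    kind: continuous
    goal: min
    support: [0.05, 0.25]
    core: [0.1, 0.15]
    weight: 0.2
  - name: convenience
    units: rank
    domain: [1, 10]
    step: 1
    kind: integer
    goal: max
    support: [6, 10]
    core: [7, 8]
    weight: 0.1
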