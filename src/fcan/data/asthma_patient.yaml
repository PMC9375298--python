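# Patient-agent preferences for the childhood-asthma case; same issue
# schema as the doctor profile, different trapezoids and weights.
agent_role: patient
issues:
  - name: cost
    units: thousand-RMB
    domain: [0, 8]
    step: 0.01
    kind: continuous
    goal: min
    support: [0, 4.5]
    core: [1, 3.5]
    weight: 0.3
  - name: effectiveness
    units: rank
    domain: [1, 10]
    step: 1
    kind: integer
    goal: max
    support: [8, 10]
    core: [9, 10]
    weight: 0.25
  - name: side_effects
    units: fraction
    domain: [0, 1]
    step: 0.01
    kind: continuous
    goal: min
    support: [0, 0.1]
    core: [0, 0.05]
    weight: 0.2
  - name: risk
    units: fraction
    domain: [0, 1]
    step: 0.01
    kind: continuous
    goal: min
    support: [0, 0.1]
    core: [0, 0.05]
    weight: 0.15
  - name: convenience
    units: rank
    domain: [1, 10]
    step: 1
    kind: integer
    goal: max
    support: [8, 10]
    core: [9, 10]
    weight: 0.1
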