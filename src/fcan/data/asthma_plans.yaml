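# Candidate step-4 childhood-asthma treatment plans with their expected
# value brackets per negotiated issue.  Side-effect and risk columns are
# written in percent and converted to fractions on load.
issues: [cost, effectiveness, side_effects, risk, convenience]
units:
  cost: thousand-RMB
  effectiveness: rank
  side_effects: percent
  risk: percent
  convenience: rank
plans:
  - name: "ICS/LABA"
    note: "en-high dose inhaled corticosteroid / long-acting beta2-agonist"
    ranges:
      cost: [2.7, 4.5]
      effectiveness: [8, 9]
      side_effects: [1, 1.5]
      risk: [1, 2]
      convenience: [9.5, 10]
  - name: "ICS+LTRA"
    note: "en-high dose inhaled corticosteroid + leukotriene receptor antagonist"
    ranges:
      cost: [4.3, 6.5]
      effectiveness: [7, 8]
      side_effects: [2, 3]
      risk: [1.5, 2.5]
      convenience: [9, 9.5]
  - name: "ICS+THP"
    note: "en-high dose inhaled corticosteroid + sustained-release theophylline"
    ranges:
      cost: [2, 4.2]
      effectiveness: [6, 7]
      side_effects: [6, 10]
      risk: [2, 2.5]
      convenience: [8, 8.5]
  - name: "ICS/LABA+LTRA"
    note: "en-high dose ICS/LABA + leukotriene receptor antagonist"
    ranges:
      cost: [5.7, 7.3]
      effectiveness: [9, 10]
      side_effects: [5, 6]
      risk: [1, 1]
      convenience: [7.5, 8]
  - name: "ICS/LABA+THP"
    note: "en-high dose ICS/LABA + sustained-release theophylline"
    ranges:
      cost: [3.5, 5]
      effectiveness: [9, 10]
      side_effects: [6, 8]
      risk: [1, 1]
      convenience: [7.5, 8]
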