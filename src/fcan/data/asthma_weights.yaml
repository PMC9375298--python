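# Issue-weight schemes used when ranking treatment plans: the doctor's
# weights, the patient's weights, and their average.
schemes:
  - name: doctor
    weights:
      cost: 0.15
      effectiveness: 0.3
      side_effects: 0.25
      risk: 0.2
      convenience: 0.1
  - name: patient
    weights:
      cost: 0.3
      effectiveness: 0.25
      side_effects: 0.2
      risk: 0.15
      convenience: 0.1
  - name: average
    weights:
      cost: 0.225
      effectiveness: 0.275
      side_effects: 0.225
      risk: 0.175
      convenience: 0.1
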