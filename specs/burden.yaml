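model_id: burden
domains: []
items:
- domain__burden_cognition
- d01
- d02
- d03
- d04
- d05
- d06
- d07
- d08
- d09
- d10
- d11
- d12
- d13
- d14
- d15
- d16
- d17
- d18
- scaled__o1
- scaled__o2
- scaled__o3
- scaled__o4
- scaled__o5
index_range:
- 0.0
- 1.0
cutoff: 0.2
age_eligibility: 70
divisor: null
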