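model_id: BS
domains:
- weight_loss
- exhaustion
- low_energy
- slowness
- weakness
items: []
index_range:
- 0.0
- 5.0
cutoff: 3.0
age_eligibility: 65
divisor: null
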