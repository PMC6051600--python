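model_id: FD
domains:
- physical
- weight_loss
- cognitive
- sensory
items: []
index_range:
- 0.0
- 4.0
cutoff: 2.0
age_eligibility: 65
divisor: null
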