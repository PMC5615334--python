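cycles,rr_data,ci_low,ci_high,rr_model_published
3,0.7,0.3,1.7,1.0
6,0.6,0.3,1.1,1.0
10,0.2,0.1,1.0,1.0
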