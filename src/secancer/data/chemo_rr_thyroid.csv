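cycles,rr_data,ci_low,ci_high,rr_model_published
5,1.8,0.3,10.0,4.61
10,9.4,1.4,56.8,6.02
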