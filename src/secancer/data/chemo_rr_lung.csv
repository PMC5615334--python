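cycles,rr_data,ci_low,ci_high,rr_model_published
3,4.0,1.3,12.5,4.1
6,6.2,2.6,17.1,7.0
10,13.0,4.3,45.0,10.6
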