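organ,scenario,dose_gy,cycles,rr_data,ci_low,ci_high,rr_model_published
thyroid,thyroid_low_medium,20,5,2.3,1.3,4.5,4.56
thyroid,thyroid_high,20,10,2.8,1.1,6.7,6.00
breast,breast,25,5,1.4,0.5,4.2,3.20
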