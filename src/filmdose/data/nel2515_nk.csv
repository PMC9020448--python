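kvp,hvl_mm,material,n_k_cgy_per_nc
100,4.14,Al,11.84
125,6.01,Al,11.87
250,17.8,Al,12.42
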