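demographic,bw_mean_kg,bw_sd_kg,ed_years
girls,62.98,21.41,9
boys,65.98,23.14,9
women,91.59,20.37,40
men,96.08,18.56,40
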