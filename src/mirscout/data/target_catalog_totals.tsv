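database	n_targets	n_mirnas_with_targets
sugarcane	1975	483
sorghum	895	373
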