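metric	icc
f_neurite	0.97
f_soma	0.98
f_extracellular	0.98
R_soma	0.94
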