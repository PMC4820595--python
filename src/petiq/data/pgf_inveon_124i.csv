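lld_keV,uld_keV,pgf
350,550,0.03
350,600,0.13
350,625,0.19
350,650,0.24
350,675,0.26
350,700,0.27
350,725,0.29
350,750,0.31
350,775,0.32
350,800,0.33
400,590,0.02
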