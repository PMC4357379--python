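gene,variant,exon,n_tumours
GNAQ,R183Q,4,1
GNAQ,Q209P,5,17
GNAQ,Q209L,5,10
GNAQ,Q209H,5,1
GNA11,Q209L,5,33
GNA11,Q209L_c626_627AG_TC,5,1
wildtype,none,,3
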