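assay,strain,cross,hatch_pct,eggs,females
mass,wRi,control-cross,89,606,31
mass,wRi,ci,10,712,41
mass,wRi,rescue,92,575,35
mass,wMel,control-cross,89,561,41
mass,wMel,ci,4,546,38
mass,wMel,rescue,92,820,42
single-pair,wRi,control-cross,90,679,35
single-pair,wRi,ci,10,672,43
single-pair,wRi,rescue,,,
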