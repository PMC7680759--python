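assay,strain,condition,hatch_pct,eggs,females
mass,wRi,ci-regular,10,454,30
mass,wRi,ci-nabu,16,292,21
mass,wRi,rescue-regular,,,
mass,wMel,ci-regular,4,382,29
mass,wMel,ci-nabu,11,544,40
mass,wMel,rescue-regular,,,
single-pair,wRi,ci-regular,10,771,30
single-pair,wRi,ci-nabu,19,724,32
single-pair,wRi,rescue-regular,94,741,30
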