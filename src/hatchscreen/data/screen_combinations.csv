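effect_class,treatment,dose,n_wells,n_plates,hit_call,p_value
Diverse functions/DNA damage,NaBu/Celastrol,25 mM/10 uM,16,2,No,0.119
Diverse functions/DNA damage,NaBu/Cycloheximide,25 mM/25 uM,16,2,No,0.817
Diverse functions/cell cycle delay,NaBu/MG132,25 mM/25 uM,16,2,No,0.201
DNA damage,Teniposide/Celastrol,250 uM/500 uM,16,2,No,0.287
DNA damage,Celastrol/Cycloheximide,10 uM/25 uM,16,2,No,0.565
DNA damage/cell cycle delay,Cycloheximide/Bortezomib,50 uM/1 uM,16,2,Yes,0.006
DNA damage/cell cycle delay,Teniposide/MG132,250 uM/25 uM,16,2,No,0.264
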