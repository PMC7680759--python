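effect_class,treatment,cellular_effect,dose,n_wells,n_plates,hit_call,p_value
Diverse functions,NaBu,C4 short chain fatty acid; affects HDACs; DNA damage repair; cell cycle,50 mM,16,2,Yes,0.011
Short chain fatty acids,Acetic acid,C2 short chain fatty acid,100 mM,16,2,No,0.408
DNA damage,Celastrol,ROS-generating,20 uM,16,2,Yes,0.013
DNA damage,Cycloheximide,Ribosome inhibitor; prevents DNA damage,50 uM,16,2,Yes,0.013
DNA damage,Teniposide,Inhibits topoisomerase II,500 uM,16,2,Borderline,0.041
Cell cycle delay,Bortezomib,Proteasome inhibitor,1 uM,16,2,Borderline,0.047
Cell cycle delay,MG132,Proteasome inhibitor,50 uM,16,2,Borderline,0.047
Cell cycle delay,Trametinib,MEK inhibitor,250 nM,16,2,No,0.096
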