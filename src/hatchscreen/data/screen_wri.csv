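effect_class,treatment,cellular_effect,dose,n_wells,n_plates,hit_call,p_value
Diverse functions,NaBu,C4 short chain fatty acid; affects HDACs; DNA damage repair; cell cycle,50 mM,16,2,Yes,<0.001
Short chain fatty acids,Acetic acid,C2 short chain fatty acid,100 mM,16,2,Borderline,0.047
Short chain fatty acids,Propionic acid,C3 short chain fatty acid,10 mM,16,2,No,0.769
Short chain fatty acids,Valeric acid,C5 short chain fatty acid,5 mM,16,2,No,0.926
Chromatin modification,Quisinostat,HDAC inhibitor,1 uM,16,2,No,0.235
Chromatin modification,Trichostatin A,HDAC inhibitor,10 uM,16,2,No,0.696
Chromatin modification,Vorinostat/SAHA,HDAC inhibitor,75 uM,16,2,No,0.913
Chromatin modification,CUDC-101,Inhibits HDACs; EGFR,250 uM,16,2,No,0.610
DNA damage,Celastrol,ROS-generating,20 uM,16,2,Yes,0.001
DNA damage,Rotenone,ROS-generating,10 uM,16,2,No,0.149
DNA damage,Cisplatin,alkylating agent,100 uM,16,2,No,0.065
DNA damage,Camptothecin,Inhibits topoisomerase I,50 uM,16,2,No,0.059
DNA damage,Teniposide,Inhibits topoisomerase II,500 uM,16,2,Yes,<0.001
DNA damage,Cycloheximide,Ribosome inhibitor; prevents DNA damage,50 uM,16,2,Yes,<0.001
Cell cycle delay,Colchicine,Destabilizes microtubules,2.5 uM,16,2,No,0.967
Cell cycle delay,Griseofulvin,Destabilizes microtubules,300 uM,16,2,No,0.675
Cell cycle delay,Taxol,Stabilizes microtubules,1 uM,16,2,No,0.774
Cell cycle delay,Apcin,APC/C inhibitor,300 uM,16,2,No,0.061
Cell cycle delay,TAME,APC inhibitor,20 mM,16,2,No,0.410
Cell cycle delay,Flavopiridol,CDK inhibitor,10 uM,16,2,No,0.360
Cell cycle delay,Roscovitine,CDK inhibitor,100 uM,16,2,No,0.175
Cell cycle delay,Bortezomib,Proteasome inhibitor,1 uM,16,2,Yes,0.005
Cell cycle delay,MG132,Proteasome inhibitor,50 uM,16,2,Yes,0.001
Cell cycle delay,Trametinib,MEK inhibitor,250 nM,16,2,Yes,0.002
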