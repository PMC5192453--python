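name,regions,label
fatty_acids,"0.9; 1.28",1
leucine_isoleucine_valine,0.98-1.05,2
lactate,1.33,3
alanine,1.48,4
acetate,1.92,5
glutamine_glutamate,"2.03; 2.16; 2.34",6
succinate,2.41,7
beta_alanine,2.56,8
dimethylamine,2.75,9
lysine,3.01,10
choline,3.22,11
glucose,"3.23-4.0; 4.62; 5.23",12
maltose,"3.5-4.0; 4.45; 5.42",13
glycerol,"4.1; 4.15",14
methyl_histidine,7.12,not shown
histidine,7.94,not shown
tyrosine,"6.89; 7.20",not shown
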