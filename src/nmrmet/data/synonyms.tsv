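alias	targets
glutamine+glutamate	glutamine;glutamate
glutamine-glutamate	glutamine;glutamate
alpha-ketoglutarate	2-oxoglutarate
akg	2-oxoglutarate
dma	dimethylamine
dimethylamine-(dma)	dimethylamine
leucine-isoleucine-valine	leucine;isoleucine;valine
methylhistidine	methyl-histidine
3-methylhistidine	methyl-histidine
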