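pathway	reaction	role	metabolite
Glycolysis and TCA cycle	hexokinase	substrate	glucose
Glycolysis and TCA cycle	hexokinase	substrate	atp
Glycolysis and TCA cycle	hexokinase	product	glucose-6-phosphate
Glycolysis and TCA cycle	hexokinase	product	adp
Glycolysis and TCA cycle	phosphoglucose-isomerase	substrate	glucose-6-phosphate
Glycolysis and TCA cycle	phosphoglucose-isomerase	product	fructose-6-phosphate
Glycolysis and TCA cycle	phosphofructokinase	substrate	fructose-6-phosphate
Glycolysis and TCA cycle	phosphofructokinase	substrate	atp
Glycolysis and TCA cycle	phosphofructokinase	product	fructose-1,6-bisphosphate
Glycolysis and TCA cycle	phosphofructokinase	product	adp
Glycolysis and TCA cycle	aldolase	substrate	fructose-1,6-bisphosphate
Glycolysis and TCA cycle	aldolase	product	glyceraldehyde-3-phosphate
Glycolysis and TCA cycle	aldolase	product	dihydroxyacetone-phosphate
Glycolysis and TCA cycle	gapdh	substrate	glyceraldehyde-3-phosphate
Glycolysis and TCA cycle	gapdh	product	1,3-bisphosphoglycerate
Glycolysis and TCA cycle	pyruvate-kinase	substrate	phosphoenolpyruvate
Glycolysis and TCA cycle	pyruvate-kinase	substrate	adp
Glycolysis and TCA cycle	pyruvate-kinase	product	pyruvate
Glycolysis and TCA cycle	pyruvate-kinase	product	atp
Glycolysis and TCA cycle	pyruvate-dehydrogenase	substrate	pyruvate
Glycolysis and TCA cycle	pyruvate-dehydrogenase	product	acetyl-coa
Glycolysis and TCA cycle	pyruvate-dehydrogenase	product	co2
Glycolysis and TCA cycle	acetyl-coa-synthetase	substrate	acetate
Glycolysis and TCA cycle	acetyl-coa-synthetase	substrate	atp
Glycolysis and TCA cycle	acetyl-coa-synthetase	product	acetyl-coa
Glycolysis and TCA cycle	acetyl-coa-synthetase	product	adp
Glycolysis and TCA cycle	citrate-synthase	substrate	acetyl-coa
Glycolysis and TCA cycle	citrate-synthase	substrate	oxaloacetate
Glycolysis and TCA cycle	citrate-synthase	product	citrate
Glycolysis and TCA cycle	aconitase	substrate	citrate
Glycolysis and TCA cycle	aconitase	product	isocitrate
Glycolysis and TCA cycle	isocitrate-dehydrogenase	substrate	isocitrate
Glycolysis and TCA cycle	isocitrate-dehydrogenase	product	2-oxoglutarate
Glycolysis and TCA cycle	isocitrate-dehydrogenase	product	co2
Glycolysis and TCA cycle	2-oxoglutarate-dehydrogenase	substrate	2-oxoglutarate
Glycolysis and TCA cycle	2-oxoglutarate-dehydrogenase	product	succinyl-coa
Glycolysis and TCA cycle	2-oxoglutarate-dehydrogenase	product	co2
Glycolysis and TCA cycle	succinyl-coa-synthetase	substrate	succinyl-coa
Glycolysis and TCA cycle	succinyl-coa-synthetase	product	succinate
Glycolysis and TCA cycle	succinate-dehydrogenase	substrate	succinate
Glycolysis and TCA cycle	succinate-dehydrogenase	product	fumarate
Glycolysis and TCA cycle	fumarase	substrate	fumarate
Glycolysis and TCA cycle	fumarase	product	malate
Glycolysis and TCA cycle	malate-dehydrogenase	substrate	malate
Glycolysis and TCA cycle	malate-dehydrogenase	product	oxaloacetate
Starch and sucrose metabolism	amylase	substrate	starch
Starch and sucrose metabolism	amylase	product	maltose
Starch and sucrose metabolism	maltase	substrate	maltose
Starch and sucrose metabolism	maltase	product	glucose
Alanine, aspartate and glutamate metabolism	glutaminase	substrate	glutamine
Alanine, aspartate and glutamate metabolism	glutaminase	product	glutamate
Alanine, aspartate and glutamate metabolism	glutamate-dehydrogenase	substrate	glutamate
Alanine, aspartate and glutamate metabolism	glutamate-dehydrogenase	product	2-oxoglutarate
Alanine, aspartate and glutamate metabolism	alanine-transaminase	substrate	alanine
Alanine, aspartate and glutamate metabolism	alanine-transaminase	substrate	2-oxoglutarate
Alanine, aspartate and glutamate metabolism	alanine-transaminase	product	pyruvate
Alanine, aspartate and glutamate metabolism	alanine-transaminase	product	glutamate
Alanine, aspartate and glutamate metabolism	aspartate-decarboxylase	substrate	aspartate
Alanine, aspartate and glutamate metabolism	aspartate-decarboxylase	product	beta-alanine
Alanine, aspartate and glutamate metabolism	aspartate-decarboxylase	product	co2
Tyrosine metabolism	tyrosine-hydroxylase	substrate	tyrosine
Tyrosine metabolism	tyrosine-hydroxylase	product	l-dopa
Tyrosine metabolism	dopa-decarboxylase	substrate	l-dopa
Tyrosine metabolism	dopa-decarboxylase	product	dopamine
Tyrosine metabolism	phenoloxidase	substrate	l-dopa
Tyrosine metabolism	phenoloxidase	product	melanin
Beta-alanine metabolism	carcinine-synthase	substrate	beta-alanine
Beta-alanine metabolism	carcinine-synthase	substrate	histamine
Beta-alanine metabolism	carcinine-synthase	product	carcinine
Beta-alanine metabolism	pantothenate-synthase	substrate	beta-alanine
Beta-alanine metabolism	pantothenate-synthase	substrate	pantoate
Beta-alanine metabolism	pantothenate-synthase	product	pantothenate
Pyruvate metabolism	lactate-dehydrogenase	substrate	pyruvate
Pyruvate metabolism	lactate-dehydrogenase	product	lactate
Glycerophospholipid metabolism	choline-kinase	substrate	choline
Glycerophospholipid metabolism	choline-kinase	substrate	atp
Glycerophospholipid metabolism	choline-kinase	product	phosphocholine
Glycerophospholipid metabolism	choline-kinase	product	adp
Glycerophospholipid metabolism	glycerol-kinase	substrate	glycerol
Glycerophospholipid metabolism	glycerol-kinase	substrate	atp
Glycerophospholipid metabolism	glycerol-kinase	product	glycerol-3-phosphate
Glycerophospholipid metabolism	glycerol-kinase	product	adp
Histidine metabolism	histidine-decarboxylase	substrate	histidine
Histidine metabolism	histidine-decarboxylase	product	histamine
Histidine metabolism	histidine-methyltransferase	substrate	histidine
Histidine metabolism	histidine-methyltransferase	product	methyl-histidine
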