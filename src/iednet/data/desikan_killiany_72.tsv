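label	roi	hemisphere	cortical
bankssts_lh	bankssts	lh	1
caudalanteriorcingulate_lh	caudalanteriorcingulate	lh	1
caudalmiddlefrontal_lh	caudalmiddlefrontal	lh	1
cuneus_lh	cuneus	lh	1
entorhinal_lh	entorhinal	lh	1
frontalpole_lh	frontalpole	lh	1
fusiform_lh	fusiform	lh	1
inferiorparietal_lh	inferiorparietal	lh	1
inferiortemporal_lh	inferiortemporal	lh	1
insula_lh	insula	lh	1
isthmuscingulate_lh	isthmuscingulate	lh	1
lateraloccipital_lh	lateraloccipital	lh	1
lateralorbitofrontal_lh	lateralorbitofrontal	lh	1
lingual_lh	lingual	lh	1
medialorbitofrontal_lh	medialorbitofrontal	lh	1
middletemporal_lh	middletemporal	lh	1
paracentral_lh	paracentral	lh	1
parahippocampal_lh	parahippocampal	lh	1
parsopercularis_lh	parsopercularis	lh	1
parsorbitalis_lh	parsorbitalis	lh	1
parstriangularis_lh	parstriangularis	lh	1
pericalcarine_lh	pericalcarine	lh	1
postcentral_lh	postcentral	lh	1
posteriorcingulate_lh	posteriorcingulate	lh	1
precentral_lh	precentral	lh	1
precuneus_lh	precuneus	lh	1
rostralanteriorcingulate_lh	rostralanteriorcingulate	lh	1
rostralmiddlefrontal_lh	rostralmiddlefrontal	lh	1
superiorfrontal_lh	superiorfrontal	lh	1
superiorparietal_lh	superiorparietal	lh	1
superiortemporal_lh	superiortemporal	lh	1
supramarginal_lh	supramarginal	lh	1
temporalpole_lh	temporalpole	lh	1
transversetemporal_lh	transversetemporal	lh	1
hippocampus_lh	hippocampus	lh	0
amygdala_lh	amygdala	lh	0
bankssts_rh	bankssts	rh	1
caudalanteriorcingulate_rh	caudalanteriorcingulate	rh	1
caudalmiddlefrontal_rh	caudalmiddlefrontal	rh	1
cuneus_rh	cuneus	rh	1
entorhinal_rh	entorhinal	rh	1
frontalpole_rh	frontalpole	rh	1
fusiform_rh	fusiform	rh	1
inferiorparietal_rh	inferiorparietal	rh	1
inferiortemporal_rh	inferiortemporal	rh	1
insula_rh	insula	rh	1
isthmuscingulate_rh	isthmuscingulate	rh	1
lateraloccipital_rh	lateraloccipital	rh	1
lateralorbitofrontal_rh	lateralorbitofrontal	rh	1
lingual_rh	lingual	rh	1
medialorbitofrontal_rh	medialorbitofrontal	rh	1
middletemporal_rh	middletemporal	rh	1
paracentral_rh	paracentral	rh	1
parahippocampal_rh	parahippocampal	rh	1
parsopercularis_rh	parsopercularis	rh	1
parsorbitalis_rh	parsorbitalis	rh	1
parstriangularis_rh	parstriangularis	rh	1
pericalcarine_rh	pericalcarine	rh	1
postcentral_rh	postcentral	rh	1
posteriorcingulate_rh	posteriorcingulate	rh	1
precentral_rh	precentral	rh	1
precuneus_rh	precuneus	rh	1
rostralanteriorcingulate_rh	rostralanteriorcingulate	rh	1
rostralmiddlefrontal_rh	rostralmiddlefrontal	rh	1
superiorfrontal_rh	superiorfrontal	rh	1
superiorparietal_rh	superiorparietal	rh	1
superiortemporal_rh	superiortemporal	rh	1
supramarginal_rh	supramarginal	rh	1
temporalpole_rh	temporalpole	rh	1
transversetemporal_rh	transversetemporal	rh	1
hippocampus_rh	hippocampus	rh	0
amygdala_rh	amygdala	rh	0
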