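# Orthologue presence of the receptor and the core angiogenic kinases
# across the jawless-fish outgroup and the 59 fixture species
# (taxa ordered oldest to youngest).
gene	lamprey	spotted_gar	zebrafish	mexican_cavefish	atlantic_cod	stickleback	fugu	tetraodon	tilapia	medaka	platyfish	amazon_molly	xenopus	caecilian	gecko	anole	python	turtle	crocodile	duck	chicken	turkey	penguin	eagle	zebra_finch	flycatcher	platypus	opossum	wallaby	tasmanian_devil	lesser_hedgehog	elephant	hyrax	sloth	armadillo	rabbit	squirrel	guinea_pig	mouse	rat	tree_shrew	mouse_lemur	bushbaby	tarsier	marmoset	macaque	baboon	vervet	gibbon	orangutan	gorilla	chimpanzee	human	hedgehog	microbat	cow	pig	horse	dog	cat
ADGRL4	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
VEGFR2	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
VEGFR1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
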