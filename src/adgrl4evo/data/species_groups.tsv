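# Major-group membership for the 59 fixture species (+ elephant shark).
species	group
spotted_gar	bony_fish
zebrafish	bony_fish
mexican_cavefish	bony_fish
atlantic_cod	bony_fish
stickleback	bony_fish
fugu	bony_fish
tetraodon	bony_fish
tilapia	bony_fish
medaka	bony_fish
platyfish	bony_fish
amazon_molly	bony_fish
xenopus	amphibian
caecilian	amphibian
gecko	reptile
anole	reptile
python	reptile
turtle	reptile
crocodile	reptile
duck	bird
chicken	bird
turkey	bird
penguin	bird
eagle	bird
zebra_finch	bird
flycatcher	bird
platypus	monotreme
opossum	marsupial
wallaby	marsupial
tasmanian_devil	marsupial
lesser_hedgehog	afrotheria
elephant	afrotheria
hyrax	afrotheria
sloth	xenarthra
armadillo	xenarthra
rabbit	rodent_lagomorph
squirrel	rodent_lagomorph
guinea_pig	rodent_lagomorph
mouse	rodent_lagomorph
rat	rodent_lagomorph
tree_shrew	tree_shrew
mouse_lemur	primate
bushbaby	primate
tarsier	primate
marmoset	primate
macaque	primate
baboon	primate
vervet	primate
gibbon	primate
orangutan	primate
gorilla	primate
chimpanzee	primate
human	primate
hedgehog	laurasiatheria
microbat	laurasiatheria
cow	laurasiatheria
pig	laurasiatheria
horse	laurasiatheria
dog	laurasiatheria
cat	laurasiatheria
elephant_shark	cartilaginous_fish
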