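# Tip variant states for the 59-tip timetree fixture.
species	variants
spotted_gar	V1
zebrafish	V1
mexican_cavefish	V1
atlantic_cod	V1
stickleback	V1,V2
fugu	V1
tetraodon	V1
tilapia	V1
medaka	V1
platyfish	V1
amazon_molly	V1
xenopus	V1,V2
caecilian	V1,V2
gecko	V1
anole	V1
python	V1
turtle	V1,V2
crocodile	V1,V2
duck	V1,V2,V3
chicken	V1
turkey	V3
penguin	V1
eagle	V1
zebra_finch	V2
flycatcher	V1
platypus	V3
opossum	V1
wallaby	V1,V2
tasmanian_devil	V1
lesser_hedgehog	V2
elephant	V2
hyrax	V2
sloth	V2
armadillo	V1
rabbit	V1
squirrel	V1
guinea_pig	V1,V2
mouse	V1
rat	V1
tree_shrew	V1
mouse_lemur	V1
bushbaby	V1
tarsier	V2
marmoset	V2
macaque	V2
baboon	V2
vervet	V2
gibbon	V2
orangutan	V2
gorilla	V2
chimpanzee	V2
human	V2
hedgehog	V1
microbat	V1,V2
cow	V2
pig	V2
horse	V2
dog	V2
cat	V2
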