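# Dated Newick, annotation dialect: [&age=mya,ci={lo,hi}].
# 59-tip vertebrate timetree fixture. The seven annotated CIs and their
# node ages are the published emergence-relevant calibrations; all other
# ages are interpolated placeholders (non-authoritative) chosen only to
# satisfy age monotonicity.
((spotted_gar[&age=0]:320,((zebrafish[&age=0]:150,mexican_cavefish[&age=0]:150)[&age=150]:80,(atlantic_cod[&age=0]:180,(stickleback[&age=0]:160,((fugu[&age=0]:50,tetraodon[&age=0]:50)[&age=50]:80,(tilapia[&age=0]:110,(medaka[&age=0]:100,(platyfish[&age=0]:60,amazon_molly[&age=0]:60)[&age=60]:40)[&age=100]:10)[&age=110]:20)[&age=130]:30)[&age=160]:20)[&age=180]:50)[&age=230]:90)[&age=320]:115,((xenopus[&age=0]:250,caecilian[&age=0]:250)[&age=250]:102,(((gecko[&age=0]:200,(anole[&age=0]:160,python[&age=0]:160)[&age=160]:40)[&age=200]:80,(turtle[&age=0]:255,(crocodile[&age=0]:240,((duck[&age=0]:80,(chicken[&age=0]:37,turkey[&age=0]:37)[&age=37,ci={28,39}]:43)[&age=80]:25,((penguin[&age=0]:60,eagle[&age=0]:60)[&age=60]:15,(zebra_finch[&age=0]:38,flycatcher[&age=0]:38)[&age=38,ci={16,43}]:37)[&age=75]:30)[&age=105]:135)[&age=240]:15)[&age=255]:25)[&age=280]:32,(platypus[&age=0]:177,((opossum[&age=0]:80,(wallaby[&age=0]:55,tasmanian_devil[&age=0]:55)[&age=55]:25)[&age=80]:79,((lesser_hedgehog[&age=0]:80,(elephant[&age=0]:65,hyrax[&age=0]:65)[&age=65]:15)[&age=80]:21,((sloth[&age=0]:66,armadillo[&age=0]:66)[&age=66,ci={60,72}]:31,(((rabbit[&age=0]:80,(squirrel[&age=0]:75,(guinea_pig[&age=0]:70,(mouse[&age=0]:20,rat[&age=0]:20)[&age=20]:50)[&age=70]:5)[&age=75]:5)[&age=80]:10,(tree_shrew[&age=0]:89,(mouse_lemur[&age=0]:88,(bushbaby[&age=0]:82,(tarsier[&age=0]:74,(marmoset[&age=0]:40,((macaque[&age=0]:14,(baboon[&age=0]:11,vervet[&age=0]:11)[&age=11]:3)[&age=14]:11,(gibbon[&age=0]:18,(orangutan[&age=0]:16,(gorilla[&age=0]:9,(chimpanzee[&age=0]:7,human[&age=0]:7)[&age=7]:2)[&age=9]:7)[&age=16]:2)[&age=18]:7)[&age=25]:15)[&age=40]:34)[&age=74]:8)[&age=82,ci={76,89}]:6)[&age=88]:1)[&age=89]:1)[&age=90]:4,(hedgehog[&age=0]:78,(microbat[&age=0]:62,((cow[&age=0]:45,pig[&age=0]:45)[&age=45]:10,(horse[&age=0]:52,(dog[&age=0]:50,cat[&age=0]:50)[&age=50]:2)[&age=52]:3)[&age=55]:7)[&age=62,ci={58,66}]:16)[&age=78]:16)[&age=94]:3)[&age=97]:4)[&age=101,ci={96,105}]:58)[&age=159]:18)[&age=177,ci={163,191}]:135)[&age=312]:40)[&age=352]:83)[&age=435];
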