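# Orthologue presence of aGPCR family-1 (ADGRL1-4) and family-2
# (ADGRE1-5) members in early vertebrates and two mammals
# (taxa ordered oldest to youngest).
gene	lamprey	bony_fish	mouse	human
ADGRL1	0	1	1	1
ADGRL2	1	1	1	1
ADGRL3	0	1	1	1
ADGRL4	0	1	1	1
ADGRE1	0	0	1	1
ADGRE2	0	0	0	1
ADGRE3	0	0	0	1
ADGRE4	0	0	1	1
ADGRE5	0	1	1	1
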