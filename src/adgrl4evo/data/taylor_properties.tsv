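# Physico-chemical amino-acid property classes after the Taylor Venn diagram
# as used by AMAS-style conservation scoring. One row per class; members are
# the residues belonging to that class. charged = positive + negative.
class	members
hydrophobic	ILVCAGMFYWHKT
polar	YWHKREQDNSTC
small	VCAGDNSTP
tiny	AGS
aliphatic	ILV
aromatic	FYWH
proline	P
positive	HKR
negative	DE
charged	HKRDE
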