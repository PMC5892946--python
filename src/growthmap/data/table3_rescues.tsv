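class	starting_strain	deleterious_mutations	rescue_mutations	medium
forward	BW25113	del_dapF	4174048 A>G;928451 C>A	LB
forward	BW25113	del_dapF	4173309 G>T;928451 C>A	LB
forward	BW25113	del_zwf	4178209 C>A;1301660 IS5(+)	LB
reverse	dapF_sup2	4173309 T>G;928451 A>C	restore dapF	M9G
reverse	dgk_sup1	4178500 T>C	restore dgk	M9G
reverse	dgk_sup2	4172748 T>C	restore dgk	M9G
reverse	entC_sup3	2374180 A>G;4178500 T>C	restore entC	M9G
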