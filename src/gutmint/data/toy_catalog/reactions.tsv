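reaction_id	metabolite_a	metabolite_b	main_pair	enzyme_ec	enzyme_name
R01	acetyl-CoA	acetate	1	2.8.3.1	propionate CoA-transferase
R02	propionate	propanoyl-CoA	1	2.8.3.1	propionate CoA-transferase
R03	lactoyl-CoA	lactate	1	2.8.3.1	propionate CoA-transferase
R04	N-formyl-L-aspartate	L-aspartate	1	3.5.1.8	N-formylaspartate amidohydrolase
R05	N-formyl-L-aspartate	formate	1	3.5.1.8	N-formylaspartate amidohydrolase
R06	L-alanine	alanyl-lactate	1	6.1.2.1	alanine-lactate ligase
R07	lactate	alanyl-lactate	1	6.1.2.1	alanine-lactate ligase
R08	lactate	acetate	1	1.13.12.4	lactate 2-monooxygenase
R09	L-valine	N-hydroxy-L-valine	1	1.14.14.38	valine N-monooxygenase
R10	L-isoleucine	N-hydroxy-L-isoleucine	1	1.14.14.38	valine N-monooxygenase
R11	beta-alanine	anserine	1	6.3.2.11	carnosine synthase
R12	3-methylhistidine	anserine	1	6.3.2.11	carnosine synthase
R13	anserine	beta-alanine	1	3.4.13.20	beta-alanine-histidine dipeptidase
R14	anserine	3-methylhistidine	1	3.4.13.20	beta-alanine-histidine dipeptidase
R15	acetate	CoA	0	2.8.3.1	propionate CoA-transferase
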