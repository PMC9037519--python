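node_type	node	direction
family	Aeromonadaceae	HC
family	Clostridiaceae	HC
family	Mycobacteriaceae	HC
family	Rhizobiaceae	HC
family	Campylobacteraceae	HC
family	Propionibacteriaceae	HC
family	ToyHC01	HC
family	ToyHC02	HC
family	ToyHC03	HC
family	ToyHC04	HC
family	ToyHC05	HC
family	ToyHC06	HC
family	ToyHC07	HC
family	Alteromonadaceae	IBS
family	Burkholderiaceae	IBS
family	Streptomycetaceae	IBS
family	ToyIBS01	IBS
family	ToyIBS02	IBS
family	ToyIBS03	IBS
family	ToyIBS04	IBS
family	ToyIBS05	IBS
family	ToyIBS06	IBS
family	ToyIBS07	IBS
family	ToyIBS08	IBS
family	ToyIBS09	IBS
family	ToyIBS10	IBS
family	ToyIBS11	IBS
metabolite	acetate	HC
metabolite	lactate	HC
metabolite	propionate	IBS
metabolite	L-aspartate	IBS
metabolite	formate	IBS
metabolite	L-alanine	IBS
metabolite	L-valine	IBS
metabolite	L-isoleucine	IBS
metabolite	beta-alanine	IBS
metabolite	3-methylhistidine	IBS
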