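organism_id	family
Aeromonadaceae_org	Aeromonadaceae
Clostridiaceae_org	Clostridiaceae
Mycobacteriaceae_org	Mycobacteriaceae
Rhizobiaceae_org	Rhizobiaceae
Campylobacteraceae_org	Campylobacteraceae
Propionibacteriaceae_org	Propionibacteriaceae
Alteromonadaceae_org	Alteromonadaceae
Burkholderiaceae_org	Burkholderiaceae
Streptomycetaceae_org	Streptomycetaceae
ToyHC01_org	ToyHC01
ToyHC02_org	ToyHC02
ToyHC03_org	ToyHC03
ToyHC04_org	ToyHC04
ToyHC05_org	ToyHC05
ToyHC06_org	ToyHC06
ToyHC07_org	ToyHC07
ToyIBS01_org	ToyIBS01
ToyIBS02_org	ToyIBS02
ToyIBS03_org	ToyIBS03
ToyIBS04_org	ToyIBS04
ToyIBS05_org	ToyIBS05
ToyIBS06_org	ToyIBS06
ToyIBS07_org	ToyIBS07
ToyIBS08_org	ToyIBS08
ToyIBS09_org	ToyIBS09
ToyIBS10_org	ToyIBS10
ToyIBS11_org	ToyIBS11
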