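enzyme_ec	organism_id
2.8.3.1	Aeromonadaceae_org
2.8.3.1	Clostridiaceae_org
2.8.3.1	Mycobacteriaceae_org
2.8.3.1	Rhizobiaceae_org
2.8.3.1	Campylobacteraceae_org
2.8.3.1	Propionibacteriaceae_org
2.8.3.1	ToyHC01_org
2.8.3.1	ToyHC02_org
2.8.3.1	ToyHC03_org
2.8.3.1	ToyHC04_org
2.8.3.1	ToyHC05_org
2.8.3.1	ToyHC06_org
2.8.3.1	ToyHC07_org
2.8.3.1	Alteromonadaceae_org
2.8.3.1	Burkholderiaceae_org
2.8.3.1	Streptomycetaceae_org
2.8.3.1	ToyIBS01_org
2.8.3.1	ToyIBS02_org
2.8.3.1	ToyIBS03_org
2.8.3.1	ToyIBS04_org
2.8.3.1	ToyIBS05_org
2.8.3.1	ToyIBS06_org
2.8.3.1	ToyIBS07_org
2.8.3.1	ToyIBS08_org
2.8.3.1	ToyIBS09_org
2.8.3.1	ToyIBS10_org
2.8.3.1	ToyIBS11_org
3.5.1.8	Aeromonadaceae_org
3.5.1.8	Clostridiaceae_org
3.5.1.8	Mycobacteriaceae_org
3.5.1.8	Rhizobiaceae_org
3.5.1.8	Campylobacteraceae_org
3.5.1.8	Propionibacteriaceae_org
3.5.1.8	Alteromonadaceae_org
3.5.1.8	Burkholderiaceae_org
3.5.1.8	Homo sapiens
6.1.2.1	Aeromonadaceae_org
6.1.2.1	Clostridiaceae_org
6.1.2.1	Mycobacteriaceae_org
6.1.2.1	Rhizobiaceae_org
6.1.2.1	Campylobacteraceae_org
6.1.2.1	Alteromonadaceae_org
6.1.2.1	Burkholderiaceae_org
6.1.2.1	Streptomycetaceae_org
1.13.12.4	Clostridiaceae_org
1.13.12.4	Rhizobiaceae_org
1.13.12.4	Propionibacteriaceae_org
1.14.14.38	Mycobacteriaceae_org
6.3.2.11	Homo sapiens
6.3.2.11	Aeromonadaceae_org
6.3.2.11	Clostridiaceae_org
6.3.2.11	Mycobacteriaceae_org
6.3.2.11	Rhizobiaceae_org
6.3.2.11	Campylobacteraceae_org
6.3.2.11	Propionibacteriaceae_org
6.3.2.11	Alteromonadaceae_org
6.3.2.11	Burkholderiaceae_org
3.4.13.20	Homo sapiens
3.4.13.20	Aeromonadaceae_org
3.4.13.20	Clostridiaceae_org
3.4.13.20	Mycobacteriaceae_org
3.4.13.20	Rhizobiaceae_org
3.4.13.20	Campylobacteraceae_org
3.4.13.20	Propionibacteriaceae_org
3.4.13.20	Alteromonadaceae_org
3.4.13.20	Burkholderiaceae_org
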