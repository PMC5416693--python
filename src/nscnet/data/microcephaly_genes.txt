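# Human primary microcephaly genes (OMIM-curated, 13 genes)
MCPH1
WDR62
ASPM
CASC5
CENPJ
CENPE
CDK5RAP1
CEP135
CEP152
STIL
CDK6
ZNF533
PHC1
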