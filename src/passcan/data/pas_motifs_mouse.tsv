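# Polyadenylation-signal hexamers annotated by the PolyASite 2.0 mouse atlas
# (the 12 classical signals plus the 6 additional signals of the extended
# inventory). Counts are representative genome-wide occurrence totals chosen
# to reproduce the atlas abundance ranking (AATAAA most abundant, ATTAAA
# second); only the rank order enters consequence classification.
# hexamer	count	abundance
AATAAA	101314	0.5103
ATTAAA	27456	0.1383
TATAAA	9437	0.0475
AGTAAA	8460	0.0426
AATATA	7802	0.0393
AATACA	7406	0.0373
CATAAA	6204	0.0312
AATGAA	5409	0.0272
GATAAA	4880	0.0246
AATAGA	3411	0.0172
AATAAT	3071	0.0155
AAGAAA	2766	0.0139
ACTAAA	2542	0.0128
AAAAAG	2227	0.0112
TTTAAA	1916	0.0096
ATTACA	1624	0.0082
ATTATA	1437	0.0072
AATAAG	1192	0.0060
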