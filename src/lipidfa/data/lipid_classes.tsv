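code	name	category	chains_per_molecule
CE	cholesteryl ester	neutral	1
MAG	monoacylglycerol	neutral	1
DAG	diacylglycerol	neutral	2
TG	triacylglycerol	neutral	3
SM	sphingomyelin	sphingolipid	1
CER	ceramide	sphingolipid	1
DCER	dihydroceramide	sphingolipid	1
HCER	hexosylceramide	sphingolipid	1
LCER	lactosylceramide	sphingolipid	1
PC	phosphatidylcholine	phospholipid	2
LPC	lysophosphatidylcholine	phospholipid	1
PE	phosphatidylethanolamine	phospholipid	2
LPE	lysophosphatidylethanolamine	phospholipid	1
PEO	phosphatidylethanolamine ether	phospholipid	2
PEP	phosphatidylethanolamine plasmalogen	phospholipid	2
PI	phosphatidylinositol	phospholipid	2
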