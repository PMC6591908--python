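metabolite_id	family	smiles
glycine	amino_acids	NCC(=O)O
alanine	amino_acids	CC(N)C(=O)O
serine	amino_acids	OCC(N)C(=O)O
threonine	amino_acids	CC(O)C(N)C(=O)O
valine	amino_acids	CC(C)C(N)C(=O)O
leucine	amino_acids	CC(C)CC(N)C(=O)O
isoleucine	amino_acids	CCC(C)C(N)C(=O)O
proline	amino_acids	OC(=O)C1CCCN1
methionine	amino_acids	CSCCC(N)C(=O)O
glutamic_acid	amino_acids	NC(CCC(=O)O)C(=O)O
aspartic_acid	amino_acids	NC(CC(=O)O)C(=O)O
glutamine	amino_acids	NC(=O)CCC(N)C(=O)O
asparagine	amino_acids	NC(=O)CC(N)C(=O)O
lysine	amino_acids	NCCCCC(N)C(=O)O
histidine	amino_acids	NC(Cc1c[nH]cn1)C(=O)O
phenylalanine	amino_acids	NC(Cc1ccccc1)C(=O)O
tyrosine	amino_acids	NC(Cc1ccc(O)cc1)C(=O)O
tryptophan	amino_acids	NC(Cc1c[nH]c2ccccc12)C(=O)O
cystine	amino_acids	NC(CSSCC(N)C(=O)O)C(=O)O
citrulline	amino_acids	NC(=O)NCCCC(N)C(=O)O
glucose	sugars	OCC1OC(O)C(O)C(O)C1O
fructose	sugars	OCC(=O)C(O)C(O)C(O)CO
ribose	sugars	OCC1OC(O)C(O)C1O
xylose	sugars	OCC(O)C(O)C(O)C=O
sorbitol	sugars	OCC(O)C(O)C(O)C(O)CO
myo_inositol	sugars	OC1C(O)C(O)C(O)C(O)C1O
glycerol	sugars	OCC(O)CO
maltose	sugars	OCC1OC(OC2C(O)C(CO)OC(O)C2O)C(O)C(O)C1O
sucrose	sugars	OCC1OC(OC2(CO)OC(CO)C(O)C2O)C(O)C(O)C1O
maltotriose	sugars	OCC1OC(OC2C(O)C(CO)OC(OC3C(O)C(CO)OC(O)C3O)C2O)C(O)C(O)C1O
oxalic_acid	organic_acids	OC(=O)C(=O)O
citric_acid	organic_acids	OC(=O)CC(O)(CC(=O)O)C(=O)O
succinic_acid	organic_acids	OC(=O)CCC(=O)O
fumaric_acid	organic_acids	OC(=O)C=CC(=O)O
malic_acid	organic_acids	OC(=O)CC(O)C(=O)O
lactic_acid	organic_acids	CC(O)C(=O)O
pyruvic_acid	organic_acids	CC(=O)C(=O)O
alpha_ketoglutaric_acid	organic_acids	OC(=O)CCC(=O)C(=O)O
glyceric_acid	organic_acids	OCC(O)C(=O)O
benzoic_acid	organic_acids	OC(=O)c1ccccc1
adenosine	nucleosides	Nc1ncnc2c1ncn2C1OC(CO)C(O)C1O
guanosine	nucleosides	Nc1nc2c(ncn2C2OC(CO)C(O)C2O)c(=O)[nH]1
uridine	nucleosides	O=c1ccn(C2OC(CO)C(O)C2O)c(=O)[nH]1
cytidine	nucleosides	Nc1ccn(C2OC(CO)C(O)C2O)c(=O)n1
inosine	nucleosides	O=c1[nH]cnc2c1ncn2C1OC(CO)C(O)C1O
hypoxanthine	nucleosides	O=c1[nH]cnc2[nH]cnc12
uric_acid	nucleosides	O=c1[nH]c(=O)c2[nH]c(=O)[nH]c2[nH]1
adenine	nucleosides	Nc1ncnc2[nH]cnc12
palmitic_acid	fatty_acids	CCCCCCCCCCCCCCCC(=O)O
stearic_acid	fatty_acids	CCCCCCCCCCCCCCCCCC(=O)O
oleic_acid	fatty_acids	CCCCCCCCC=CCCCCCCCC(=O)O
myristic_acid	fatty_acids	CCCCCCCCCCCCCC(=O)O
lauric_acid	fatty_acids	CCCCCCCCCCCC(=O)O
linoleic_acid	fatty_acids	CCCCCC=CCC=CCCCCCCCC(=O)O
capric_acid	fatty_acids	CCCCCCCCCC(=O)O
arachidic_acid	fatty_acids	CCCCCCCCCCCCCCCCCCCC(=O)O
palmitoleic_acid	fatty_acids	CCCCCCC=CCCCCCCCC(=O)O
cholesterol	sterols	CC(C)CCCC(C)C1CCC2C1(C)CCC1C2CCC2=CC(O)CCC12C
campesterol	sterols	CC(C)C(C)CCC(C)C1CCC2C1(C)CCC1C2CCC2=CC(O)CCC12C
glucose_6_phosphate	phosphates	OC1OC(COP(=O)(O)O)C(O)C(O)C1O
phosphoglycerate_3	phosphates	OC(COP(=O)(O)O)C(=O)O
pyrophosphate	phosphates	OP(=O)(O)OP(=O)(O)O
adenosine_5_phosphate	phosphates	Nc1ncnc2c1ncn2C1OC(COP(=O)(O)O)C(O)C1O
phosphoenolpyruvate	phosphates	C=C(OP(=O)(O)O)C(=O)O
glycerol_3_phosphate	phosphates	OCC(O)COP(=O)(O)O
urea	amines	NC(N)=O
creatinine	amines	CN1CC(=O)NC1=N
choline	amines	C[N+](C)(C)CCO
putrescine	amines	NCCCCN
taurine	amines	NCCS(=O)(=O)O
ethanolamine	amines	NCCO
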