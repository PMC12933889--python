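# Natural-product-like exemplars: sugars, glycosides, terpenoids, steroids,
# alkaloids, amino acids and other saturated, stereocenter-rich chemotypes.
OC[C@H]1O[C@@H](O)[C@H](O)[C@@H](O)[C@@H]1O	glucose
OC[C@H]1O[C@](O)(CO)[C@@H](O)[C@@H]1O	fructose
OC[C@H]1O[C@@H](O[C@H]2[C@H](O)[C@@H](O)C(O)O[C@@H]2CO)[C@H](O)[C@@H](O)[C@@H]1O	disaccharide
OC[C@@H](O)[C@@H](O)[C@H](O)[C@H](O)CO	sorbitol
O[C@H]1C[C@@H](O)[C@H](O)[C@@H](O)C1	quercitol
CC(C)=CCC/C(C)=C/CO	geraniol
CC(C)=CCC/C(C)=C/CC/C(C)=C/CO	farnesol
CC1=CC[C@@H](C(C)C)CC1	terpinene
CC(C)[C@@H]1CC[C@@H](C)C[C@H]1O	menthol
CC1(C)[C@@H]2CC[C@@]1(C)C(=O)C2	camphor
CC1(C)[C@@H]2CC[C@@H]1C(=C)C2	pinene-like
C[C@H]1CC[C@H]2[C@@H](C)CCC[C@H]2C1	decalin-dimethyl
C[C@]12CC[C@H]3[C@@H](CC[C@H]4C[C@H](O)CC[C@]34C)[C@@H]1CC[C@@H]2O	androstanediol
C[C@]12CC[C@H]3[C@@H](CCC4=CC(=O)CC[C@]34C)[C@@H]1CC[C@@H]2O	testosterone-like
CC(C)CCC[C@@H](C)[C@H]1CC[C@H]2[C@@H]3CC[C@H]4C[C@H](O)CC[C@]4(C)[C@H]3CC[C@]12C	cholestanol
C[C@H](N)C(=O)O	alanine
CC(C)[C@H](N)C(=O)O	valine
N[C@@H](CC(C)C)C(=O)O	leucine
N[C@@H](CO)C(=O)O	serine
N[C@@H](CCC(=O)O)C(=O)O	glutamate
O=C(O)[C@@H]1CCCN1	proline
N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O	tryptophan
CN1CC[C@H]2[C@@H]1Cc1c[nH]c3cccc2c13	ergoline-core
CN1[C@H]2CC[C@@H]1C[C@@H](O)C2	tropanol
CN1[C@H]2CC[C@@H]1C[C@@H](OC(=O)C(CO)c1ccccc1)C2	atropine-like
C[C@@H]1CC[C@@H]2[C@@H](C1)CCN2C	pyrrolidine-alkaloid
CN1CCC[C@H]1c1cccnc1	nicotine
O=C1C[C@@H]2CC[C@H](C1)N2	quinuclidinone-like
OC[C@H]1NC[C@@H](O)[C@@H](O)[C@@H]1O	iminosugar
O[C@@H]1[C@@H](O)[C@H](O)[C@@H](O)[C@H](O)[C@H]1O	inositol
C[C@H]1O[C@H](O)[C@H](O)[C@@H](O)[C@H]1O	rhamnose
CC(=O)N[C@H]1[C@@H](O)O[C@H](CO)[C@@H](O)[C@@H]1O	glcnac
O=C1O[C@H](CO)[C@@H](O)C1=O	ascorbate-like
CC(C)[C@H]1CC[C@](C)(O)CC1	terpineol-like
C/C=C/C=C/C(=O)O[C@H]1C[C@@H](O)[C@H](O)C[C@H]1O	shikimate-ester
O=C(O)C1=C[C@@H](O)[C@H](O)[C@@H](O)C1	shikimic-acid
C[C@@H]1CC[C@H]2C(C)(C)[C@@H]3C[C@@H](O)[C@]2(C)[C@H]1C3	sesquiterpenol
CC1(C)CC[C@@H]2[C@](C)(CC[C@H]3[C@@]2(C)CC[C@@H]2[C@]3(C)CC[C@@H](O)C2(C)C)C1	triterpenoid-core
O=C1C[C@H](O)[C@@H](O)[C@@H](CO)O1	lactone-sugar
C[C@H](O)[C@H](O)[C@@H](O)C=O	erythrose-methyl
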