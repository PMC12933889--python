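# Synthetic-compound exemplars: flat (hetero)aromatic chemotypes, biaryls,
# sulfonamides, ureas, anilides -- achiral, aromatic-ring rich.
c1ccc(-c2ccccc2)cc1	biphenyl
c1ccc(-c2ccncc2)cc1	phenylpyridine
c1ccc(-c2ccc3ccccc3c2)cc1	phenylnaphthalene
c1ccc2ccccc2c1	naphthalene
c1ccc2cc3ccccc3cc2c1	anthracene
c1ccc(Oc2ccccc2)cc1	diphenylether
c1ccc(Nc2ccccc2)cc1	diphenylamine
O=C(Nc1ccccc1)c1ccccc1	benzanilide
O=C(Nc1ccccc1)Nc1ccccc1	diphenylurea
O=S(=O)(Nc1ccccc1)c1ccccc1	benzenesulfonanilide
O=S(=O)(N)c1ccc(-c2ccccc2)cc1	biphenylsulfonamide
Cc1ccc(-c2ccc(C)cc2)cc1	ditolyl
COc1ccc(-c2ccccc2)cc1	methoxybiphenyl
Clc1ccc(-c2ccccc2)cc1	chlorobiphenyl
Fc1ccc(-c2ccc(F)cc2)cc1	difluorobiphenyl
[O-][N+](=O)c1ccc(-c2ccccc2)cc1	nitrobiphenyl
N#Cc1ccc(-c2ccccc2)cc1	cyanobiphenyl
c1ccc(-c2nc3ccccc3[nH]2)cc1	phenylbenzimidazole
c1ccc(-c2nc3ccccc3s2)cc1	phenylbenzothiazole
c1ccc(-c2nc3ccccc3o2)cc1	phenylbenzoxazole
c1ccc(-c2ccc3ncccc3c2)cc1	phenylquinoline
c1cnc2ccccc2c1	quinoline
c1ccc2ncccc2c1	isoquinoline-like
c1ccc2[nH]ccc2c1	indole
c1ccc2occc2c1	benzofuran
c1ccc2sccc2c1	benzothiophene
c1ccc(-n2cccn2)cc1	phenylpyrazole
c1ccc(-c2cccnn2)cc1	phenylpyridazine-like
c1ccc(-c2ncccn2)cc1	phenylpyrimidine
c1ccc(-c2cnccn2)cc1	phenylpyrazine
O=C(c1ccccc1)c1ccccc1	benzophenone
C(=C/c1ccccc1)\c1ccccc1	stilbene
C(#Cc1ccccc1)c1ccccc1	diphenylacetylene
O=C(O)c1ccc(-c2ccccc2)cc1	biphenylcarboxylate
Cn1cnc2ccccc21	methylbenzimidazole
c1ccc(-c2ccc(-c3ccccc3)cc2)cc1	terphenyl
O=[N+]([O-])c1ccc(N)cc1	nitroaniline
Nc1ccc(-c2ccccc2)cc1	aminobiphenyl
O=C(Nc1ccc(Cl)cc1)c1cccnc1	chloroanilide-pyridine
O=S(=O)(Nc1ccccn1)c1ccc(N)cc1	sulfapyridine-like
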