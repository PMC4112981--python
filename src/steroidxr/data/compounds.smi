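# Curated 2D structures for the packaged steroid immunoassay panels.
# Format: SMILES <whitespace> name (name may contain spaces).
# Structures are transcribed from canonical structure references in neutral,
# largest-fragment form except where noted; stereo descriptors are retained
# where they distinguish catalogue epimers (the standardizer removes them).
# Sulfate conjugates are bundled as the neutral (protonated) acids so that
# fingerprints are charge-state independent; estropipate is bundled as the
# full estrone sulfate / piperazine salt to exercise salt stripping.
OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C	cortisol
OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CC(C)C2=CC(=O)C=CC12C	6-methylprednisolone
OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2CC(O)CCC12C	allotetrahydrocortisol
OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CC(O)C2=CC(=O)CCC12C	6beta-hydroxycortisol
OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2=CC(=O)C=CC12C	prednisolone
CC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C	21-deoxycortisol
OCC(=O)C1(O)CCC2C1(C)CC(O)C1(F)C2CCC2=CC(=O)CCC12C	fludrocortisone
OCC(=O)C1CCC2C1(C)CC(O)C1C2CCC2CC(=O)CCC12C	5beta-dihydrocorticosterone
OCC(=O)C1CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C	corticosterone
OCC(=O)C1(O)CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12C	11-deoxycortisol
CC12CCC3C(C1CCC24CCC(=O)O4)C=CC1=CC(=O)CCC31C	canrenone
CC(=O)C1(O)CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12C	17-hydroxyprogesterone
O=C1CCC2(C)C(=C1O)CCC1C2CCC2(C)C1CCC2=O	formestane
O=C1CCC2(C)C(=C1)CCC1C2CCC2(C)C1CCC2=O	androstenedione
OCC(=O)C1(O)CCC2C1(C)CC(=O)C1C2CCC2=CC(=O)C=CC12C	prednisone
OCC(=O)C1(O)CCC2C1(C)CC(=O)C1C2CCC2CC(O)CCC12C	tetrahydrocortisone
CC12CCC3C(CC=C4CC(OS(=O)(=O)O)CCC34C)C1CCC2=O	DHEA sulfate
CC(=O)C1CCC2C1(C)CCC1C2CC=C2CC(OS(=O)(=O)O)CCC12C	pregnenolone sulfate
CC(=O)C1(O)CCC2C1(C)CCC1C2CC=C2CC(O)CCC12C	17-hydroxypregnenolone
CC12CCC3c4ccc(OS(=O)(=O)O)cc4CCC3C1CCC2=O.C1CNCCN1	estropipate
CC12CCC3c4ccc(O)cc4CCC3C1CCC2O	estradiol
CC12CCC3c4ccc(O)cc4CCC3C1CCC2=O	estrone
C#CC1(O)CCC2C1(C)CCC1c3ccc(O)cc3CCC21	ethinyl estradiol
CC12CCC3c4ccc(O)cc4CCC3C1CC(O)C2O	estriol
COc1cc2c(cc1O)CCC1C2CCC2(C)C1CCC2O	2-methoxyestradiol
N#Cc1ccc(C(n2cncn2)c2ccc(C#N)cc2)cc1	letrozole
CC(=O)C1CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12C	progesterone
CC(=O)C1CCC2C1(C)CCC1C2CCC2CC(=O)CCC12C	5beta-dihydroprogesterone
CC(=O)C1CCC2C1(C)CCC1C2CC[C@H]2C[C@H](O)CCC12C	pregnanolone
CC(=O)C1CCC2C1(C)CCC1C2CC[C@@H]2C[C@H](O)CCC12C	allopregnanolone
CC(=O)C1CCC2C1(C)CCC1C2CCC2CC(O)CCC12C	5alpha-pregnan-3-ol-20-one
CC(=O)C1CCC2C1(C)CCC1C2CC[C@@H]2CC(=O)CCC12C	5alpha-pregnan-3,20-dione
CC(=O)C1CCC2C1(C)CCC1C2CC[C@@H]2C[C@@H](O)CCC12C	5alpha-pregnenolone
CC(=O)C1(O)CCC2C1(C)CCC1C2CC(C)C2=CC(=O)CCC12C	medroxyprogesterone
CC(=O)C1CCC2C1(C)CCC1C2CC=C2CC(O)CCC12C	pregnenolone
C=C1CC2C(CCC3(C)C2CCC3=O)C2(C)C=CC(=O)C=C12	exemestane
OC1CCC2(C)C1CCC1C2CCC2=CC(=O)CCC12	nandrolone
CC12CCC3C(CCC4=CC(=O)CCC34C)C1CCC2O	testosterone
CC12CCC3C(CCC4=CC(=O)CCC34C)C1CCC2(C)O	methyltestosterone
CC12CCC3C(CCC4=CC(=O)C=CC34C)C1CCC2O	boldenone
OC1CCC2(C)C1CCC1C2CCC2=C(Cl)C(=O)CCC12	19-norclostebol
C#CC1(O)CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12	norethindrone
CC12CC(O)C3C(CCC4=CC(=O)CCC34C)C1CCC2O	11beta-hydroxytestosterone
CC12CCC3C(CCC4=CC(=O)C=CC34C)C1CCC2(C)O	methandrostenolone
CC1(O)CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12	normethandrolone
CCC(=O)OC1CCC2(C)C1CCC1C2CCC2=CC(=O)CCC12C	testosterone propionate
CC12CCC3C(CCC4Cc5[nH]ncc5CC34C)C1CCC2(C)O	stanozolol
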