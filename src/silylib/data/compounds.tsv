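name	datasets	smiles	flags	note
nitroxoline	tms_only	Oc1ccc([N+](=O)[O-])c2cccnc12		
17α-hydroxyprogesterone	tms_only	CC(=O)C1(O)CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12C		
6β-hydroxypregnenolone	tms_only	CC(=O)C1CCC2C1(C)CCC1C2C(O)C2=CC(O)CCC2(C)C1	uncertain	ring-B unsaturation position approximate
5-androstene-3β,17β-diol	tms_only	OC1CCC2C1(C)CCC1C2CC=C2CC(O)CCC12C		
boldenone	tms_only	OC1CCC2C1(C)CCC1C2CCC2=CC(=O)C=CC12C		
11α-hydroxytestosterone	tms_only	OC1CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C		
11α-hydroxyandrostenedione	tms_only	O=C1CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C		
methamphetamine	tms_only	CNC(C)Cc1ccccc1		
nylidrin	tms_only	OC(c1ccc(O)cc1)C(C)NC(C)CCc1ccccc1		
quinic acid	tms_only	OC1CC(O)(C(=O)O)CC(O)C1O		
shikimic acid	tms_only	OC1CC(=CC(O)C1O)C(=O)O		
meso-erythritol	tms_only	OCC(O)C(O)CO		
amphetamine	tms_only	CC(N)Cc1ccccc1		
6-nitroguaiacol	tms_only	COc1cccc([N+](=O)[O-])c1O		
estriol	tms_only	Oc1ccc2c(c1)CCC1C2CCC2(C)C1CC(O)C2O		
codeine	tms_only	COc1ccc2CC3N(C)CCC45C(Oc1c24)C(O)C=CC35		
L-tyrosine	tms_only	NC(Cc1ccc(O)cc1)C(=O)O		
L-ascorbic acid	tms_only	OCC(O)C1OC(=O)C(O)=C1O		
cannabidiolic acid	tms_only	CCCCCc1cc(O)c(C2CC(C)=CCC2C(=C)C)c(O)c1C(=O)O		
bisphenol FL	tms_only	Oc1ccc(cc1)C1(c2ccc(O)cc2)c2ccccc2-c2ccccc21		
butylated hydroxytoluene	tms_only	Cc1cc(C(C)(C)C)c(O)c(C(C)(C)C)c1		
4,6-dinitroguaiacol	tbdms_only	COc1cc([N+](=O)[O-])cc([N+](=O)[O-])c1O		
mycophenolic acid	tbdms_only	Cc1c(CC=C(C)CCC(=O)O)c(O)c2COC(=O)c2c1OC		
bisphenol A	both	CC(C)(c1ccc(O)cc1)c1ccc(O)cc1		
benzoic acid	both	OC(=O)c1ccccc1		
mecoprop	both	CC(Oc1ccc(Cl)cc1C)C(=O)O		
4,4′-biphenol	both	Oc1ccc(-c2ccc(O)cc2)cc1		
4,4′-dihydroxydiphenyl ether	both	Oc1ccc(Oc2ccc(O)cc2)cc1		
4,4′-isopropylidenebis(2,6-dimethylphenol)	both	CC(C)(c1cc(C)c(O)c(C)c1)c1cc(C)c(O)c(C)c1		
2,4′-dihydroxydiphenylmethane	both	Oc1ccc(Cc2ccccc2O)cc1		
bisphenol AF	both	OC1=CC=C(C=C1)C(c1ccc(O)cc1)(C(F)(F)F)C(F)(F)F		
bisphenol AP	both	CC(c1ccccc1)(c1ccc(O)cc1)c1ccc(O)cc1		
bisphenol C	both	CC(C)(c1ccc(O)c(C)c1)c1ccc(O)c(C)c1		
bisphenol E	both	CC(c1ccc(O)cc1)c1ccc(O)cc1		
bisphenol F	both	Oc1ccc(Cc2ccc(O)cc2)cc1		
bisphenol M	both	CC(C)(c1ccc(O)cc1)c1cccc(C(C)(C)c2ccc(O)cc2)c1		
bisphenol BP	both	Oc1ccc(C(c2ccccc2)(c2ccccc2)c2ccc(O)cc2)cc1		
bisphenol P	both	CC(C)(c1ccc(O)cc1)c1ccc(C(C)(C)c2ccc(O)cc2)cc1		
bisphenol S	both	Oc1ccc(S(=O)(=O)c2ccc(O)cc2)cc1		
bisphenol Z	both	Oc1ccc(C2(c3ccc(O)cc3)CCCCC2)cc1		
2,2′-methylenediphenol	both	Oc1ccccc1Cc1ccccc1O		
stanolone	both	OC1CCC2C1(C)CCC1C2CCC2CC(=O)CCC12C		
11-hydroxy-Δ9-tetrahydrocannabinol	both	CCCCCc1cc(O)c2c(c1)OC(C)(C)C1CCC(CO)=CC21		
11-nor-9-carboxy-Δ9-tetrahydrocannabinol	both	CCCCCc1cc(O)c2c(c1)OC(C)(C)C1CCC(C(=O)O)=CC21		
sulfanilamide	both	Nc1ccc(S(N)(=O)=O)cc1		
adipic acid	both	OC(=O)CCCCC(=O)O		
4-tert-octylphenol	both	CC(C)(C)CC(C)(C)c1ccc(O)cc1		
9-hydroxyfluorene	both	OC1c2ccccc2-c2ccccc21		
L-leucine	both	CC(C)CC(N)C(=O)O		
L-serine	both	NC(CO)C(=O)O		
Δ9-tetrahydrocannabinol	both	CCCCCc1cc(O)c2c(c1)OC(C)(C)C1CCC(C)=CC21		
Δ9-tetrahydrocannabinolic acid	both	CCCCCc1cc(O)c2c(c1C(=O)O)OC(C)(C)C1CCC(C)=CC21		
trans-3′-hydroxycotinine	both	CN1C(=O)CC(O)C1c1cccnc1		
benzoylecgonine	both	CN1C2CCC1C(C(=O)O)C(OC(=O)c1ccccc1)C2		
bisphenol CL	both	Oc1ccc(C(=C(Cl)Cl)c2ccc(O)cc2)cc1	uncertain	identity taken as 1,1-dichloro-2,2-bis(4-hydroxyphenyl)ethylene
bisphenol PH	both	CC(C)(c1ccc(O)c(-c2ccccc2)c1)c1ccc(O)c(-c2ccccc2)c1	uncertain	identity taken as 5,5'-(propane-2,2-diyl)bis(biphenyl-2-ol)
8-hydroxyquinoline	both	Oc1cccc2cccnc12		
2-anilinophenylacetic acid	both	OC(=O)Cc1ccccc1Nc1ccccc1		
4-nitroguaiacol	both	COc1cc([N+](=O)[O-])ccc1O		
5-nitroguaiacol	both	COc1ccc([N+](=O)[O-])cc1O		
catechol	both	Oc1ccccc1O		
3-methylcatechol	both	Cc1cccc(O)c1O		
3-methyl-5-nitrocatechol	both	Cc1cc([N+](=O)[O-])cc(O)c1O		
2-benzyl-4-chlorophenol	both	Oc1ccc(Cl)cc1Cc1ccccc1		
citric acid monohydrate	both	OC(=O)CC(O)(CC(=O)O)C(=O)O		anhydrous structure recorded; hydrate water omitted
4-cumylphenol	both	CC(C)(c1ccccc1)c1ccc(O)cc1		
2,4-dihydroxybenzophenone	both	Oc1ccc(C(=O)c2ccccc2)c(O)c1		
estrone	both	Oc1ccc2c(c1)CCC1C2CCC2(C)C1CCC2=O		
17β-estradiol	both	Oc1ccc2c(c1)CCC1C2CCC2(C)C1CCC2O		
m-coumaric acid	both	OC(=O)C=Cc1cccc(O)c1		
p-coumaric acid	both	OC(=O)C=Cc1ccc(O)cc1		
o-coumaric acid	both	OC(=O)C=Cc1ccccc1O		
triclosan	both	Oc1cc(Cl)ccc1Oc1ccc(Cl)cc1Cl		
cannabidiol	both	CCCCCc1cc(O)c(C2CC(C)=CCC2C(=C)C)c(O)c1		
cannabinol	both	CCCCCc1cc(O)c2c(c1)OC(C)(C)c1ccc(C)cc12		
cannabichromene	both	CCCCCc1cc(O)c2C=CC(C)(CCC=C(C)C)Oc2c1		
morphine	both	Oc1ccc2CC3N(C)CCC45C(Oc1c24)C(O)C=CC35		
6-monoacetylmorphine	both	CC(=O)OC1C=CC2C(CC3N(C)CCC234)c2ccc(O)c(O1)c24		
carbamazepine	both	NC(=O)N1c2ccccc2C=Cc2ccccc21		
isopropylparaben	both	CC(C)OC(=O)c1ccc(O)cc1		
bisphenol B	both	CCC(C)(c1ccc(O)cc1)c1ccc(O)cc1		
17α-ethynylestradiol	both	C#CC1(O)CCC2C1(C)CCC1c3ccc(O)cc3CCC21		
4-hydroxybenzophenone	both	Oc1ccc(C(=O)c2ccccc2)cc1		
2,2′-dihydroxy-4-methoxybenzophenone	both	COc1ccc(C(=O)c2ccccc2O)c(O)c1		
clofibric acid	both	CC(C)(Oc1ccc(Cl)cc1)C(=O)O		
ibuprofen	both	CC(C)Cc1ccc(C(C)C(=O)O)cc1		
naproxen	both	COc1ccc2cc(C(C)C(=O)O)ccc2c1		
ketoprofen	both	CC(C(=O)O)c1cccc(C(=O)c2ccccc2)c1		
diclofenac	both	OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl		
methylparaben	both	COC(=O)c1ccc(O)cc1		
ethylparaben	both	CCOC(=O)c1ccc(O)cc1		
propylparaben	both	CCCOC(=O)c1ccc(O)cc1		
butylparaben	both	CCCCOC(=O)c1ccc(O)cc1		
isobutylparaben	both	CC(C)COC(=O)c1ccc(O)cc1		
benzylparaben	both	O=C(OCc1ccccc1)c1ccc(O)cc1		
4-nonylphenol	both	CCCCCCCCCc1ccc(O)cc1		
phenylacetic acid	both	OC(=O)Cc1ccccc1		
resorcinol	both	Oc1cccc(O)c1		
salicylic acid	both	OC(=O)c1ccccc1O		
urea	both	NC(N)=O		
4-nitrocatechol	both	Oc1ccc([N+](=O)[O-])cc1O		
syringol	both	COc1cccc(OC)c1O		
4-nitrosyringol	both	COc1cc([N+](=O)[O-])cc(OC)c1O		
etofylline	both	Cn1c(=O)c2c(ncn2CCO)n(C)c1=O		
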