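table_name	compound	n_groups	rt_min	flags	note
benzoic acid TBDMS	benzoic acid	1	8.139		
benzoylecgonine TBDMS	benzoylecgonine	1	17.724		
benzeneacetic acid TBDMS	phenylacetic acid	1	8.433		printed 'benzeneacetic acid'
cannabichromene TBDMS	cannabichromene	1	17.851		
methylparaben TBDMS	methylparaben	1	10.327		
citric acid TBDMS	citric acid monohydrate	1	17.956		
8-hydroquinone TBDMS	8-hydroxyquinoline	1	10.738	uncertain	printed '8-hydroquinone'; read as 8-hydroxyquinoline
tetrahydrocannabinol TBDMS	Δ9-tetrahydrocannabinol	1	18.04		
clofibric acid TBDMS	clofibric acid	1	11.011		
3,4-dehydro TBDMS		1	18.093	uncertain	printed '3,4-dehydroTBDMS'; identity unresolved, attached to no compound
ethylparaben TBDMS	ethylparaben	1	11.032		
cannabidiol TBDMS	cannabidiol	1	18.566		
resorcinol TBDMS	resorcinol	1	11.074		printed 'TBMDS'
DHDPE TBDMS	4,4′-dihydroxydiphenyl ether	1	18.587		printed 'DHDPE'
isopropylparaben TBDMS	isopropylparaben	1	11.316		
bisphenol F TBDMS	bisphenol F	1	18.619		
ibuprofen TBDMS	ibuprofen	1	11.401		
bisphenol E TBDMS	bisphenol E	1	18.756		
mecoprop TBDMS	mecoprop	1	11.506		
4,4′-bisphenol TBDMS	4,4′-biphenol	1	18.787		printed '4,4'-bisphenol'
4-tertoctylphenol TBDMS	4-tert-octylphenol	1	11.727		
bisphenol 8 TBDMS	2,2′-dihydroxy-4-methoxybenzophenone	1	18.798		printed 'bisphenol 8' (BP-8)
propylparaben TBDMS	propylparaben	1	12.032		
cannabinol TBDMS	cannabinol	1	18.819		
salicylic acid TBDMS	salicylic acid	1	12.379		
bisphenol A TBDMS	bisphenol A	1	18.977		
adipic acid TBDMS	adipic acid	1	12.442		
morphine TBDMS	morphine	1	19.134		
isobutylparaben TBDMS	isobutylparaben	1	12.59		
bisphenol B TBDMS	bisphenol B	1	19.566		
butylparaben TBDMS	butylparaben	1	13.063		printed 'butytlparaben'
bisphenol C TBDMS	bisphenol C	1	19.639		printed 'bipshenol C'
4-nonylphenol TBDMS	4-nonylphenol	1	14.462		
6-monoacetylmorphine TBDMS	6-monoacetylmorphine	1	20.008		
9-hydroxyfluorene TBDMS	9-hydroxyfluorene	1	13.463		
estrone TBDMS	estrone	1	20.534		printed 'TBMDS'
erythritol TBDMS	meso-erythritol	1	13.61	uncertain	meso-erythritol is a TMS-only compound in the inventory; row attached to no derivative
bisphenol CL TBDMS	bisphenol CL	1	20.839		
trans-3′-hydroxycotinine TBDMS	trans-3′-hydroxycotinine	1	14.042		
BP26DM TBDMS	4,4′-isopropylidenebis(2,6-dimethylphenol)	1	20.86		printed 'BP26DM'
4-cumylphenol TBDMS	4-cumylphenol	1	14.273		
11-hydroxytetrahydrocannabinol TBDMS	11-hydroxy-Δ9-tetrahydrocannabinol	1	21.144		
chlorophene TBDMS	2-benzyl-4-chlorophenol	1	14.389		printed 'chlorophene'
ethinyl estradiol TBDMS	17α-ethynylestradiol	1	21.144		
4-hydroxybenzophenone TBDMS	4-hydroxybenzophenone	1	15.725		
tetrahydrocannabinolic acid TBDMS	Δ9-tetrahydrocannabinolic acid	1	21.249		
naproxen TBDMS	naproxen	1	15.757		
bisphenol Z TBDMS	bisphenol Z	1	21.733		
triclosan TBDMS	triclosan	1	16.199		printed 'tricolsan'
11-nor-9-tetrahydrocannabinol TBDMS	11-nor-9-carboxy-Δ9-tetrahydrocannabinol	1	22.154		
sulfanilamide TBDMS	sulfanilamide	1	16.399		
bisphenol S TBDMS	bisphenol S	1	22.607		
2,2-bisphenol F TBDMS	2,2′-methylenediphenol	1	16.578		
bisphenol AP TBDMS	bisphenol AP	1	22.649		
ketoprofen TBDMS	ketoprofen	1	16.883		
estradiol TBDMS	17β-estradiol	1	23.059		
benzylparaben TBDMS	benzylparaben	1	16.925		
bisphenol M TBDMS	bisphenol M	1	24.185		
bisphenol AF TBDMS	bisphenol AF	1	17.114		
bisphenol P TBDMS	bisphenol P	1	26.479		
carbamazepine TBDMS	carbamazepine	1	17.356		
bisphenol PH TBDMS	bisphenol PH	1	27.079		
2,4-bisphenol F TBDMS	2,4′-dihydroxydiphenylmethane	1	17.63		printed '2.4-bisphenol F'
bisphenol BP TBDMS	bisphenol BP	1	27.457		
diclofenac TBDMS	diclofenac	1	17.693		
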