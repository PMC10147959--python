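table_name	compound	n_groups	rt_min	method	flags	note
benzoic acid TMS	benzoic acid	1	6.669	1		
propylparaben TMS	propylparaben	1	10.3	1		
methylparaben TMS	methylparaben	1	8.93	1		
isobutylparaben TMS	isobutylparaben	1	10.73	1		
salicylic acid-bis TMS	salicylic acid	2	9.02	1		
butylparaben TMS	butylparaben	1	11.08	1		
ethylparaben TMS	ethylparaben	1	9.52	1		
shikimic acid TMS	shikimic acid	1	11.26	1		
isopropylparaben TMS	isopropylparaben	1	9.76	1		
quinic acid TMS	quinic acid	1	11.62	1		
ibuprofen TMS	ibuprofen	1	9.96	1		
triclosan TMS	triclosan	1	13.56	1		
mecoprop TMS	mecoprop	1	10.04	1		
benzylparaben TMS	benzylparaben	1	13.84	1		
cannabidiol TMS	cannabidiol	1	14.2	1		
resorcinol TMS	resorcinol	1	6.75	2		
carbamazepine TMS	carbamazepine	1	12.36	2		
clofibric acid TMS	clofibric acid	1	8.07	2		
diclofenac TMS	diclofenac	1	12.53	2		
9-hydroxyfluorene TMS	9-hydroxyfluorene	1	9.44	2		
cannabichromene TMS	cannabichromene	1	12.805	2		
4-cumylphenol TMS	4-cumylphenol	1	9.883	2		
Δ9-tetrahydrocannabinol TMS	Δ9-tetrahydrocannabinol	1	13.041	2		
naproxen TMS	naproxen	1	11.07	2		
cannabinol TMS	cannabinol	1	13.63	2		
4-nonylphenol TMS	4-nonylphenol	1	10.01	2		
Δ9-tetrahydrocannabinolic acid TMS	Δ9-tetrahydrocannabinolic acid	1	14.882	2		
2,4-dihydroxybenzophenone TMS	2,4-dihydroxybenzophenone	1	11.13	2		
estrone 2TMS	estrone	2	14.882	2	enol	second TMS on the 17-keto enol
4,4′-biphenol 2TMS	4,4′-biphenol	2	11.49	2		
estradiol TMS	17β-estradiol	1	15.083	2		
ketoprofen TMS	ketoprofen	1	11.51	2		
ethinylestradiol TMS	17α-ethynylestradiol	1	15.142	2		
sulfanilamide 2TMS	sulfanilamide	2	11.91	2		
estriol 3TMS	estriol	3	16.145	2		
2,2′-dihydroxy-4-methoxybenzophenone TMS	2,2′-dihydroxy-4-methoxybenzophenone	1	12.108	2		
phenylacetic acid TMS	phenylacetic acid	1	6.203	3		
bisphenol E 2TMS	bisphenol E	2	11.692	3		
bisphenol A 2TMS	bisphenol A	2	11.874	3		
catechol 2TMS	catechol	2	6.329	3		
L-serine TMS	L-serine	1	11.902	3	extra_row	single TMS row; inventory lists one L-serine TMS derivative (3TMS)
L-serine 3TMS	L-serine	3	6.571	3		
bisphenol C 2TMS	bisphenol C	2	11.932	3		
syringol TMS	syringol	1	6.908	3		
bisphenol B 2TMS	bisphenol B	2	12.462	3		
3-methtylcatechol TMS	3-methylcatechol	1	6.928	3		printed '3-methtylcatechol'
benzoylecgonine TMS	benzoylecgonine	1	12.582	3		
urea 2TMS	urea	2	7.124	3		
methamphetamine TMS	methamphetamine	1	12.59	3		
erythritol 4TMS	meso-erythritol	4	7.542	3		
4,4′-isopropylidenebis(2,6-dimethylphenol) TMS	4,4′-isopropylidenebis(2,6-dimethylphenol)	1	13.432	3		
adipic acid TMS	adipic acid	1	7.632	3		
bisphenol CL 2TMS	bisphenol CL	2	13.571	3		
8-hydroxyquinoline TMS	8-hydroxyquinoline	1	7.803	3		
nylidrin TMS	nylidrin	1	13.579	3		
6-nitroguaiacol TMS	6-nitroguaiacol	1	8.202	3		
codeine TMS	codeine	1	13.811	3		
4-octylphenol TMS	4-tert-octylphenol	1	8.45	3		
morphine 2TMS	morphine	2	14.112	3		
4-nitroguaiacol TMS	4-nitroguaiacol	1	8.623	3		
bisphenol Z 2TMS	bisphenol Z	2	14.462	3		
5-nitroguaiacol TMS	5-nitroguaiacol	1	8.728	3		
6-monoacetylmorphine TMS	6-monoacetylmorphine	1	14.562	3		
4-nitrocatechol TMS	4-nitrocatechol	1	9.044	3		
5-androstene-3β,17β-diol TMS	5-androstene-3β,17β-diol	1	14.599	3		
citric acid TMS	citric acid monohydrate	1	9.33	3		
quinic acid TMS	quinic acid	1	14.623	3	duplicate	re-listed under oven program (3)
p-coumaric acid TMS	p-coumaric acid	1	9.359	3		
5-androstene-3β,17β-diol 2TMS	5-androstene-3β,17β-diol	2	14.641	3		
4-nitrosyringol TMS	4-nitrosyringol	1	9.475	3		
11-hydroxytetrahydrocannabinol 2TMS	11-hydroxy-Δ9-tetrahydrocannabinol	2	14.652	3		
3-methyl-5-nitrocatechol TMS	3-methyl-5-nitrocatechol	1	9.538	3		
stanolone TMS	stanolone	1	14.757	3		
L-leucine TMS	L-leucine	1	9.629	3		
stanolone 2TMS	stanolone	2	14.873	3	enol	second TMS on the 3-keto enol
m-coumaric acid TMS	m-coumaric acid	1	9.728	3		
bisphenol S 2TMS	bisphenol S	2	14.971	3		
butylated hydroxytoluene TMS	butylated hydroxytoluene	1	9.722	3		
bisphenol AP 2TMS	bisphenol AP	2	15.183	3		
trans-3’-hydroxycotinine TMS	trans-3′-hydroxycotinine	1	9.842	3		
boldenone TMS	boldenone	1	15.42	3		
clorophene TMS	2-benzyl-4-chlorophenol	1	10.002	3		printed 'clorophene'
11-nor9-tetrahydrocannabinol 2TMS	11-nor-9-carboxy-Δ9-tetrahydrocannabinol	2	15.553	3		
o-coumaric acid TMS	o-coumaric acid	1	10.085	3		
L-tyrosine TMS	L-tyrosine	1	15.704	3		
nitroxoline TMS	nitroxoline	1	10.149	3		
L-ascorbic acid TMS	L-ascorbic acid	1	15.846	3		
2,2-bisphenol F 2TMS	2,2′-methylenediphenol	2	10.231	3		
11α-hydroxyandrostenedione TMS	11α-hydroxyandrostenedione	1	15.988	3		
bisphenol AF TMS	bisphenol AF	1	10.492	3		
11α-hydroxytestosterone TMS	11α-hydroxytestosterone	1	16.188	3		
amphetamine TMS	amphetamine	1	10.551	3		
bisphenol M 2TMS	bisphenol M	2	16.193	3		
2,4-bisphenol F 2TMS	2,4′-dihydroxydiphenylmethane	2	10.863	3		
6β-hydroxypregnenolone TMS	6β-hydroxypregnenolone	1	16.693	3		
2-anilinophenylacetic acid TMS	2-anilinophenylacetic acid	1	10.885	3		
17α-hydroxyprogesterone TMS	17α-hydroxyprogesterone	1	17.135	3		
2,4-dihydroxybenzophenone TMS	2,4-dihydroxybenzophenone	1	11.132	3	duplicate	re-listed under oven program (3)
bisphenol P 2TMS	bisphenol P	2	17.242	3		
shikimic acid TMS	shikimic acid	1	11.271	3	duplicate	re-listed under oven program (3)
bisphenol BP 2TMS	bisphenol BP	2	17.695	3		
etofylline TMS	etofylline	1	11.253	3		
bisphenol PH 2TMS	bisphenol PH	2	17.832	3		
4,4′-dihydroxydiphenyl ether 2TMS	4,4′-dihydroxydiphenyl ether	2	11.423	3		
cannabidiolic acid TMS	cannabidiolic acid	1	18.269	3		
bisphenol F 2TMS	bisphenol F	2	11.512	3		
bisphenol FL 2TMS	bisphenol FL	2	18.902	3		
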