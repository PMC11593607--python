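name,chem_class,aliases
arsenic,heavy_metal,As;inorganic arsenic;iAs
cadmium,heavy_metal,Cd
lead,heavy_metal,Pb
mercury,heavy_metal,Hg;methylmercury
acenaphthene,PAH,Ace
acenaphthylene,PAH,Acy
anthracene,PAH,Ant
benz[a]anthracene,PAH,B[a]A;benzo[a]anthracene;BaA
benzo[a]pyrene,PAH,B[a]P;BaP
benzo[b]fluoranthene,PAH,B[b]F;BbF
benzo[j]fluoranthene,PAH,B[j]F;BjF
benzo[k]fluoranthene,PAH,B[k]F;BkF
benzo[ghi]perylene,PAH,"B[ghi]P;benzo[g,h,i]perylene"
chrysene,PAH,Chr
cyclopenta[cd]pyrene,PAH,CPP
dibenz[ah]anthracene,PAH,"D[ah]A;dibenz[a,h]anthracene"
fluoranthene,PAH,Fla;Flu
fluorene,PAH,F
indeno[123-cd]pyrene,PAH,"IP;indeno[1,2,3-cd]pyrene"
naphthalene,PAH,Nap
phenanthrene,PAH,Phe
pyrene,PAH,P;Pyr
acetamiprid,pesticide,ACET
chlorpyrifos,pesticide,CPF
chlorpyrifos-methyl,pesticide,CPFm
cypermethrin,pesticide,CYP
deltamethrin,pesticide,DEL
lambda-cyhalothrin,pesticide,CYH;λ-cyhalothrin;lambda cyhalothrin
methomyl,pesticide,MET
propiconazole,pesticide,PCZ
pyraclostrobin,pesticide,PYR
tebuconazole,pesticide,TEB
aflatoxin B1,mycotoxin,AFB1
alternariol,mycotoxin,AOH
alternariol methyl ether,mycotoxin,AME;alternariol monomethyl ether
beauvericin,mycotoxin,BEA
citrinin,mycotoxin,CIT
deoxynivalenol,mycotoxin,DON;vomitoxin
enniatin A,mycotoxin,ENN A;ENNA
enniatin A1,mycotoxin,ENN A1;ENNA1
enniatin B,mycotoxin,ENN B;ENNB
enniatin B1,mycotoxin,ENN B1;ENNB1
ergocornine,mycotoxin,
ergocristine,mycotoxin,
ergokryptine,mycotoxin,ergocryptine
ergokryptinine,mycotoxin,ergocryptinine
ergometrine,mycotoxin,ergonovine
ergonisine,mycotoxin,
ergosine,mycotoxin,
ergotamine,mycotoxin,
ergotaminine,mycotoxin,
fumonisin B1,mycotoxin,FB1
fusaric acid,mycotoxin,FA
HT-2 toxin,mycotoxin,HT2;HT-2
moniliformin,mycotoxin,MON
nivalenol,mycotoxin,NIV
ochratoxin A,mycotoxin,OTA
sterigmatocystin,mycotoxin,STER;STC
T-2 toxin,mycotoxin,T2;T-2
tenuazonic acid,mycotoxin,TeA
zearalenone,mycotoxin,ZEN;ZEA
harman,HAA,H;harmane
norharman,HAA,NH;norharmane
PhIP,HAA,"2-amino-1-methyl-6-phenylimidazo[4,5-b]pyridine"
MeIQx,HAA,"2-amino-3,8-dimethylimidazo[4,5-f]quinoxaline;8-MeIQx"
MeIQ,HAA,"2-amino-3,4-dimethylimidazo[4,5-f]quinoline"
IQ,HAA,"2-amino-3-methyl-3H-imidazo[4,5-f]quinoline"
IQx,HAA,"3-methyl-3H-imidazo[4,5-f]quinoxalin-2-amine"
4-8-diMeIQx,HAA,"4,8-diMeIQx;4,8dMQx;2-amino-3,4,8-trimethylimidazo[4,5-f]quinoxaline"
7-8-diMeIQx,HAA,"7,8-diMeIQx;7,8dMQx;2-amino-3,7,8-trimethylimidazo[4,5-f]quinoxaline"
AalphaC,HAA,AαC;2-amino-alpha-carboline
MeAalphaC,HAA,MeAαC;2-amino-3-methyl-alpha-carboline
Trp-P-1,HAA,TrpP1
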