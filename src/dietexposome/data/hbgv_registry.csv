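contaminant,gtype,value,units,period,endpoint,moe_threshold
cadmium,TWI,2.5,ug,week,renal toxicity,
mercury,TWI,4,ug,week,developmental neurotoxicity,
arsenic,BMDL05,0.06,ug,day,skin cancer,1
lead,BMDL01,0.5,ug,day,developmental neurotoxicity,
lead,BMDL01,1.5,ug,day,systolic blood pressure,
lead,BMDL10,0.63,ug,day,nephrotoxicity,
acetamiprid,ADI,0.025,mg,day,,
cypermethrin,ADI,0.005,mg,day,,
deltamethrin,ADI,0.01,mg,day,,
chlorpyrifos,ADI,0.001,mg,day,,
methomyl,ADI,0.02,mg,day,,
propiconazole,ADI,0.07,mg,day,,
pyraclostrobin,ADI,0.03,mg,day,,
tebuconazole,ADI,0.03,mg,day,,
lambda-cyhalothrin,ADI,0.005,mg,day,,
deoxynivalenol,TDI,1,ug,day,,
fumonisin B1,TDI,0.1,ug,day,,
nivalenol,TDI,1.2,ug,day,,
T-2 toxin,TDI,0.1,ug,day,,
zearalenone,TDI,0.25,ug,day,,
ochratoxin A,BMDL10,4.73,ug,day,non-neoplastic,200
ochratoxin A,BMDL10,14.5,ug,day,neoplastic,10000
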