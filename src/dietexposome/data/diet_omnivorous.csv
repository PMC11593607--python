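food,mass_g_day,energy_kcal_day,group
rice,200,250,whole_grains
wheat,200,204,whole_grains
maize,200,376,whole_grains
potato,50,44,tubers_starchy_vegetables
cabbage,200,44,vegetables
carrot,150,38,vegetables
apple,200,122,fruits
cheese,60,148,dairy_foods
beef,90,173,animal_protein_sources
salmon,120,328,animal_protein_sources
beans,40,41,other_protein_sources
peanuts,20,121,other_protein_sources
olive oil,50,450,added_fats
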