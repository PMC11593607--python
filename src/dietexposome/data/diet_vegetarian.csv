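food,mass_g_day,energy_kcal_day,group
rice,160,200,whole_grains
wheat,160,163,whole_grains
maize,160,301,whole_grains
potato,40,35,tubers_starchy_vegetables
cabbage,200,44,vegetables
carrot,150,38,vegetables
apple,200,122,fruits
cheese,70,173,dairy_foods
egg,120,179,animal_protein_sources
beans,200,206,other_protein_sources
peanuts,80,484,other_protein_sources
olive oil,40,360,added_fats
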