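component,category,points,threshold,cmp
energy_kj,general,1,335,gt
energy_kj,general,2,670,gt
energy_kj,general,3,1005,gt
energy_kj,general,4,1340,gt
energy_kj,general,5,1675,gt
energy_kj,general,6,2010,gt
energy_kj,general,7,2345,gt
energy_kj,general,8,2680,gt
energy_kj,general,9,3015,gt
energy_kj,general,10,3350,gt
energy_kj,beverage,1,0,gt
energy_kj,beverage,2,30,gt
energy_kj,beverage,3,60,gt
energy_kj,beverage,4,90,gt
energy_kj,beverage,5,120,gt
energy_kj,beverage,6,150,gt
energy_kj,beverage,7,180,gt
energy_kj,beverage,8,210,gt
energy_kj,beverage,9,240,gt
energy_kj,beverage,10,270,gt
sugars_g,general,1,4.5,gt
sugars_g,general,2,9,gt
sugars_g,general,3,13.5,gt
sugars_g,general,4,18,gt
sugars_g,general,5,22.5,gt
sugars_g,general,6,27,gt
sugars_g,general,7,31,gt
sugars_g,general,8,36,gt
sugars_g,general,9,40,gt
sugars_g,general,10,45,gt
sugars_g,beverage,1,0,gt
sugars_g,beverage,2,1.5,gt
sugars_g,beverage,3,3,gt
sugars_g,beverage,4,4.5,gt
sugars_g,beverage,5,6,gt
sugars_g,beverage,6,7.5,gt
sugars_g,beverage,7,9,gt
sugars_g,beverage,8,10.5,gt
sugars_g,beverage,9,12,gt
sugars_g,beverage,10,13.5,gt
satfat_g,general,1,1,gt
satfat_g,general,2,2,gt
satfat_g,general,3,3,gt
satfat_g,general,4,4,gt
satfat_g,general,5,5,gt
satfat_g,general,6,6,gt
satfat_g,general,7,7,gt
satfat_g,general,8,8,gt
satfat_g,general,9,9,gt
satfat_g,general,10,10,gt
satfat_ratio_pct,added_fat,1,10,ge
satfat_ratio_pct,added_fat,2,16,ge
satfat_ratio_pct,added_fat,3,22,ge
satfat_ratio_pct,added_fat,4,28,ge
satfat_ratio_pct,added_fat,5,34,ge
satfat_ratio_pct,added_fat,6,40,ge
satfat_ratio_pct,added_fat,7,46,ge
satfat_ratio_pct,added_fat,8,52,ge
satfat_ratio_pct,added_fat,9,58,ge
satfat_ratio_pct,added_fat,10,64,ge
sodium_mg,general,1,90,gt
sodium_mg,general,2,180,gt
sodium_mg,general,3,270,gt
sodium_mg,general,4,360,gt
sodium_mg,general,5,450,gt
sodium_mg,general,6,540,gt
sodium_mg,general,7,630,gt
sodium_mg,general,8,720,gt
sodium_mg,general,9,810,gt
sodium_mg,general,10,900,gt
fruitveg_pct,general,1,40,gt
fruitveg_pct,general,2,60,gt
fruitveg_pct,general,5,80,gt
fruitveg_pct,beverage,2,40,gt
fruitveg_pct,beverage,4,60,gt
fruitveg_pct,beverage,10,80,gt
fibre_g,general,1,0.9,gt
fibre_g,general,2,1.9,gt
fibre_g,general,3,2.8,gt
fibre_g,general,4,3.7,gt
fibre_g,general,5,4.7,gt
protein_g,general,1,1.6,gt
protein_g,general,2,3.2,gt
protein_g,general,3,4.8,gt
protein_g,general,4,6.4,gt
protein_g,general,5,8,gt
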