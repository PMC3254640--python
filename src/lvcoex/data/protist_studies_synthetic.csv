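# Synthetic illustrative coordinates for eight published two-species protist
# coexistence experiments. The original reports present these states only
# graphically; values here were constructed to reproduce the qualitative
# region of each study (below / on / above the RYT line, or a positive
# interaction) and carry no quantitative authority.
study_id,species1,species2,alone1,alone2,coexist1,coexist2,units,source
1,Colpidium striatum,Paramecium aurelia,8.44e7,6.92e7,3.53e7,4.09e7,um3_biovolume,synthetic_this_system
2,Blepharisma americana,Paramecium tetraurelia,10.0,8.0,13.0,3.2,mg_biomass,synthetic
3,Colpidium striatum,Tetrahymena thermophyla,20.0,15.0,8.0,5.25,mg_biomass,synthetic
4,Chilomonas paramecium,Colpidium striatum,4.0,6.0,2.0,7.5,mg_biomass,synthetic_low_nutrient
5,Chilomonas paramecium,Colpidium striatum,9.0,11.0,5.4,15.4,mg_biomass,synthetic_high_nutrient
6,Colpidium striatum,Paramecium tetraurelia,12.0,10.0,8.4,6.0,mg_biomass,synthetic_22C
7,Colpidium striatum,Paramecium tetraurelia,12.0,10.0,5.4,4.0,mg_biomass,synthetic_30C
8,Paramecium aurelia,Paramecium caudatum,14.0,9.0,7.7,2.7,mg_biomass,synthetic
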