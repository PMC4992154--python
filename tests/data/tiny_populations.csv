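species_id,island_id,class_volancy,body_mass,extirpated,extant,single_island_endemic
S1,A,volant_bird,35.0,1,0,1
S2,A,reptile,,0,1,1
S3,B,nonvolant_mammal,420.0,0,1,0
S3,C,nonvolant_mammal,420.0,1,0,0
S4,C,amphibian,12.0,0,1,1
S5,C,nonvolant_bird,95.0,0,1,1
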