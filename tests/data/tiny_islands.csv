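island_id,area,elevation,precipitation,mean_temperature,temperature_seasonality,human_presence,canids,felids,mustelids_mongooses,pigs,primates,medium_omnivores,small_omnivores,rats,mice,large_herbivores,medium_herbivores,lagomorphs,eradicated_rats
A,0.5,5.0,800.0,24.0,2.0,0,0,0,0,0,0,0,0,1,0,0,0,0,1
B,12.0,80.0,1300.0,21.0,3.0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
C,250.0,600.0,2100.0,18.0,4.5,1,0,1,0,1,0,0,0,1,0,0,0,0,0
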