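study,ref,female_pct,age_min,age_max,population,route,doses_mg,n,weight_mean_kg,weight_sd_kg,weight_note
1,B30,45,18,45,healthy,oral,50,11,68.1,7.1,sd
1,B30,45,18,45,healthy,iv,25,11,68.1,7.1,sd
2,B35,48,18,45,healthy,oral,25;50;100;200,60,58.6,5.6,sd
3,B38,65,18,45,healthy,oral,25;50;100;200,20,70.9,8.6,sd
4,B37,0,18,45,healthy,oral,100,4,85.0,,range_77_93
5,B36,56,18,85,mild,oral,50,96,63.1,,average
5,B36,62,18,85,moderate,oral,50,96,62.4,,average
5,B36,61,18,85,severe,oral,50,96,63.7,,average
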