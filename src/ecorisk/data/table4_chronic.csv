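species,taxon_group,endpoint,exposure_class,duration_hours,value_ugL,ci_low,ci_high,source
Dunaliella tertiolecta,algae,NOEC,chronic,72,0.48,,,this study
Skeletonema marinoi-dohrnii complex,algae,NOEC,chronic,72,0.45,,,this study
Tetraselmis tetrathele,algae,NOEC,chronic,72,1.2,,,this study (reference value)
Mummichog,fish,LOEC,chronic,1320,3.9,,,literature (55 d)
Mummichog,fish,NOEC,chronic,1320,2.1,,,literature (55 d)
Mummichog,fish,MATC,chronic,1320,2.9,,,literature (55 d)
Spotted halibut,fish,EC50,chronic,240,8.1,7.5,8.8,literature (10 d)
Spotted halibut,fish,LOEC,chronic,240,8.5,,,literature (10 d)
Spotted halibut,fish,NOEC,chronic,240,6.7,,,literature (10 d)
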