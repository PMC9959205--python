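species,taxon_group,endpoint,exposure_class,duration_hours,value_ugL,ci_low,ci_high,source
Dunaliella tertiolecta,algae,EC50,acute,72,3.0,2.2,3.7,this study
Skeletonema marinoi-dohrnii complex,algae,EC50,acute,72,0.72,0.63,0.82,this study
Tetraselmis tetrathele,algae,EC50,acute,72,12,10,14,this study (reference value; control growth below criterion)
Japanese blue crab,crustacean,EC50,acute,24,16,6.2,25,this study
Tigriopus japonicus,crustacean,EC50,acute,24,2.0,1.4,4.5,this study
Marbled flounder,fish,LC50,acute,96,331,,,geometric mean of two 96 h LC50s (source prints the mean with an inconsistent mg/L unit; stored as ug/L)
Mummichog,fish,LC50,acute,96,88,,,geometric mean of four 96 h LC50s (larvae and juveniles)
Red sea bream,fish,LC50,acute,96,25.5,,,geometric mean of two 96 h LC50s
Spotted halibut,fish,LC50,acute,96,363,,,geometric mean of two 96 h LC50s
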