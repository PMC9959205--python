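species,taxon_group,endpoint,exposure_class,duration_hours,value_ugL,ci_low,ci_high,source
Dunaliella tertiolecta,algae,EC50,acute,72,3.0,2.2,3.7,this study
Skeletonema marinoi-dohrnii complex,algae,EC50,acute,72,0.72,0.63,0.82,this study
Tetraselmis tetrathele,algae,EC50,acute,72,12,10,14,this study (reference value)
Japanese blue crab,crustacean,EC50,acute,24,16,6.2,25,this study
Tigriopus japonicus,crustacean,EC50,acute,24,2.0,1.4,4.5,this study
Marbled flounder,fish,LC50,acute,96,301,190,413,literature
Marbled flounder,fish,LC50,acute,96,363,153,575,literature
Mummichog,fish,LC50,acute,96,12,10,14,literature (larval)
Mummichog,fish,LC50,acute,96,13,8.2,22,literature (larval)
Mummichog,fish,LC50,acute,96,540,220,870,literature (juvenile)
Mummichog,fish,LC50,acute,96,710,670,760,literature (juvenile)
Red sea bream,fish,LC50,acute,96,29.2,11.2,47.3,literature
Red sea bream,fish,LC50,acute,96,22.4,9.9,35.0,literature
Spotted halibut,fish,LC50,acute,96,239,121,356,literature
Spotted halibut,fish,LC50,acute,96,553,552,554,literature
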