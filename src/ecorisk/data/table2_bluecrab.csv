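label,nominal_ugL,measured_start_ugL,measured_end_ugL,geomean_ugL,detection_limit_ugL,is_control,is_solvent_control,n_exposed,n_immobile
Control,0,,,,0.2,1,0,20,2
SC,0,,,,0.2,0,1,20,2
10,10,7.2,2.79,4.5,0.2,0,0,20,2
20,20,13,4.3,7.4,0.2,0,0,20,7
40,40,25,7.0,13,0.2,0,0,20,12
80,80,48,22,32,0.2,0,0,20,12
160,160,80,27,46,0.2,0,0,20,14
320,320,166,31,72,0.2,0,0,20,16
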