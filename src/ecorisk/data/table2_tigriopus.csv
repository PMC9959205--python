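label,nominal_ugL,measured_start_ugL,measured_end_ugL,geomean_ugL,detection_limit_ugL,is_control,is_solvent_control,n_exposed,n_immobile
Control,0,,,,0.2,1,0,20,0
SC,0,0.6,0.2,0.3,0.2,0,1,20,1
2.5,2.5,1.7,0.5,0.9,0.2,0,0,18,4
5,5,3.1,1.6,2.2,0.2,0,0,21,10
10,10,6.5,2.5,4.0,0.2,0,0,20,17
20,20,12.0,3.6,6.5,0.2,0,0,20,20
40,40,23.2,7.7,13.3,0.2,0,0,20,20
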