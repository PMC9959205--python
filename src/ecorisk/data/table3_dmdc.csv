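label,nominal_ugL,measured_start_ugL,measured_end_ugL,geomean_ugL,detection_limit_ugL,is_control,is_solvent_control,density0_mean,density0_se,density_end_mean,density_end_se,rate_mean,rate_se,inhibition_mean,inhibition_se,significant
Control,0,,,,0.02,1,0,1.1,0.0,85.8,5.0,1.45,0.02,0,1,0
SC,0,0.10,,,0.02,0,1,1.2,0.0,95.0,2.9,1.45,0.01,0,1,0
2.5,2.5,0.41,0.07,0.17,0.02,0,0,1.2,0.0,89.7,2.4,1.45,0.01,0,1,0
3.5,3.5,0.81,0.28,0.48,0.02,0,0,1.2,0.0,75.6,14.8,1.38,0.08,5,5,0
5,5,1.64,0.38,0.79,0.02,0,0,1.1,0.0,21.6,8.2,0.93,0.12,36,8,1
7,7,1.96,0.92,1.35,0.02,0,0,1.2,0.0,0.9,0.1,-0.07,0.03,105,2,1
10,10,2.30,1.90,2.09,0.02,0,0,1.3,0.0,0.3,0.0,-0.46,0.02,131,1,1
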