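label,nominal_ugL,measured_start_ugL,measured_end_ugL,geomean_ugL,detection_limit_ugL,is_control,is_solvent_control,density0_mean,density0_se,density_end_mean,density_end_se,rate_mean,rate_se,inhibition_mean,inhibition_se,significant
Control,0,,,,0.04,1,0,1.1,0.0,85.8,5.0,1.45,0.02,5,1,0
SC,0,0.07,,,0.04,0,1,1.1,0.0,109.6,2.8,1.53,0.01,0,1,0
3.5,3.5,0.81,0.11,0.29,0.04,0,0,1.1,0.0,106.8,1.2,1.53,0.00,0,0,0
5,5,1.40,0.14,0.45,0.04,0,0,1.1,0.0,94.3,4.6,1.50,0.02,2,1,0
7,7,1.77,0.24,0.65,0.04,0,0,1.1,0.0,29.9,9.3,1.06,0.10,30,7,1
10,10,3.11,1.77,2.34,0.04,0,0,1.2,0.0,1.0,0.3,-0.11,0.14,108,9,1
14,14,5.24,4.15,4.66,0.04,0,0,1.3,0.0,0.2,0.0,-0.68,0.01,145,1,1
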