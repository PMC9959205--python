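label,nominal_ugL,measured_start_ugL,measured_end_ugL,geomean_ugL,detection_limit_ugL,is_control,is_solvent_control,density0_mean,density0_se,density_end_mean,density_end_se,rate_mean,rate_se,inhibition_mean,inhibition_se,significant
Control,0,,,,0.04,1,0,1.0,0.0,16.5,0.3,0.93,0.01,1,1,0
SC,0,,,,0.04,0,1,1.0,0.0,17.0,0.2,0.94,0.01,0,1,0
2.5,2.5,0.34,0.05,0.13,0.04,0,0,1.0,0.0,15.9,0.2,0.92,0.00,3,0,0
5,5,1.00,0.23,0.48,0.04,0,0,1.0,0.0,14.3,0.3,0.88,0.01,7,1,0
10,10,2.04,0.43,0.94,0.04,0,0,1.0,0.0,10.0,0.7,0.76,0.02,19,2,1
20,20,4.63,1.33,2.48,0.04,0,0,1.0,0.0,6.7,0.6,0.62,0.03,35,3,1
40,40,11.05,3.19,5.94,0.04,0,0,1.1,0.0,1.9,0.2,0.17,0.04,82,4,1
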