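label,nominal_ugL,measured_start_ugL,measured_end_ugL,geomean_ugL,detection_limit_ugL,is_control,is_solvent_control,density0_mean,density0_se,density_end_mean,density_end_se,rate_mean,rate_se,inhibition_mean,inhibition_se,significant
Control,0,,,,0.04,1,0,0.85,0.07,13.1,1.0,0.89,0.02,2,2,0
SC,0,,,,0.04,0,1,0.85,0.01,13.2,0.2,0.91,0.01,0,1,0
5,5,2.36,0.57,1.16,0.04,0,0,0.86,0.01,12.6,0.3,0.89,0.01,3,1,0
10,10,4.55,1.26,2.39,0.04,0,0,0.87,0.01,9.2,0.6,0.77,0.02,15,2,1
20,20,10.23,4.59,6.85,0.04,0,0,0.98,0.02,5.5,0.1,0.58,0.00,37,0,1
40,40,20.26,9.26,13.70,0.04,0,0,1.25,0.06,4.2,0.2,0.41,0.01,55,1,1
80,80,39.10,22.48,29.64,0.04,0,0,1.25,0.12,3.0,0.3,0.27,0.03,70,4,1
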