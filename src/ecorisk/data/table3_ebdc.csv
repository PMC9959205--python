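label,nominal_ugL,measured_start_ugL,measured_end_ugL,geomean_ugL,detection_limit_ugL,is_control,is_solvent_control,density0_mean,density0_se,density_end_mean,density_end_se,rate_mean,rate_se,inhibition_mean,inhibition_se,significant
Control,0,,,,0.02,1,0,1.1,0.0,85.8,5.0,1.45,0.02,0,1,0
SC,0,,,,0.02,0,1,1.0,0.0,86.1,3.5,1.46,0.02,0,1,0
7,7,,,,0.02,0,0,1.0,0.0,71.1,5.2,1.40,0.03,4,1,0
10,10,,,,0.02,0,0,1.0,0.0,61.3,6.5,1.36,0.04,7,3,0
14,14,,,,0.02,0,0,1.0,0.0,42.3,6.3,1.23,0.05,16,3,1
20,20,,,,0.02,0,0,1.0,0.0,0.4,0.1,-0.33,0.07,122,5,1
28,28,,,,0.02,0,0,1.0,0.0,0.1,0.0,-0.67,0.02,146,1,1
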