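distribution,anderson_darling,kolmogorov_smirnov,cramer_von_mises,aic,aicc,bic,delta_aicc,aicc_weight
gamma,0.456,0.217,0.0740,96.2,98.2,96.6,1.23,0.145
lgumbel,0.237,0.153,0.0337,95.3,97.3,95.7,0.406,0.218
llogis,0.234,0.138,0.0301,95.7,97.7,96.1,0.787,0.180
llogis_llogis,0.159,0.138,0.0243,91.8,112,92.8,14.9,0.00
lnorm,0.245,0.141,0.0315,94.9,96.9,95.3,0.00,0.267
lnorm_lnorm,0.160,0.139,0.0237,91.0,111,92.0,14.0,0.00
weibull,0.334,0.168,0.0470,95.6,97.6,96.0,0.692,0.189
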