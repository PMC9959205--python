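analyte,location,concentration_ugL
polycarbamate,Hiroshima Bay,0.11
DMDC,Hiroshima Bay,0.043
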