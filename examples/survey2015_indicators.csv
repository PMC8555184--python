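group,medicines_per_encounter,pct_antibiotic,pct_injection,pct_generic,pct_eml,pct_dispensed,pct_labelled
overall,3.1,23.8,1.2,35.5,68.8,92.4,98.5
private,2.9,27.1,1.8,32.4,69.5,93.5,97.7
state_owned,3.6,15.0,1.1,40.6,67.8,89.8,99.4
spc_franchise,3.1,25.6,0.6,35.2,68.7,93.2,98.8
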