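# EEG band table: name f_low f_high (Hz); artifact defaults
delta	1	4
theta	4	8
alpha	8	12
beta	12	30
gamma	30	80
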