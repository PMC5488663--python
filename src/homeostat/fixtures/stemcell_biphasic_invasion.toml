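# The same sensing-dead mutant under biphasic renewal control: at its
# (low) sensed signal renewal drops below one half and it is eliminated.
kind = "stemcell"
seed = 0

[initial]
Z_s = 0.5
Z_s_mut = 0.0
Z_d = 1.0

[model]
law = "biphasic"
mutant_time = 10.0
mutant_mass = 0.01
fold = 0.0625
horizon = 100.0
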