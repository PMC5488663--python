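# A four-fold activating mis-senser introduced into the monophasic circuit:
# it has positive growth at the set point and sweeps the tissue.
kind = "invade"
seed = 0

[circuit]
preset = "monophasic"

[initial]
Z = 5.0
y = 4.0

[run]
horizon = 200.0

[[schedule.clones]]
fold = 4.0
time = 10.0
mass = 1.0
label = "mut_t10"
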