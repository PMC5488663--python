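# Two four-fold mis-sensers introduced into the biphasic circuit at t=10
# and t=47; each senses past the unstable threshold and is eliminated.
kind = "invade"
seed = 0

[circuit]
preset = "biphasic"

[initial]
Z = 6.16
y = 4.06

[run]
horizon = 200.0

[[schedule.clones]]
fold = 4.0
time = 10.0
mass = 1.0
label = "mut_t10"

[[schedule.clones]]
fold = 4.0
time = 47.0
mass = 1.0
label = "mut_t47"
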