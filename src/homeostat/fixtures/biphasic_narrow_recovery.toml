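# The sharper biphasic circuit (smaller stable-unstable gap): higher
# evolutionary stability, narrower perturbation tolerance.
kind = "simulate"
seed = 0

[circuit]
preset = "biphasic_narrow"

[initial]
Z = 5.5
y = 4.5

[run]
horizon = 200.0
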