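# Biphasic toy circuit converging to its stable fixed point (~4.06, ~6.16).
kind = "simulate"
seed = 0

[circuit]
preset = "biphasic"

[initial]
Z = 5.0
y = 5.0

[run]
horizon = 200.0
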