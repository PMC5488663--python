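# Monophasic toy circuit recovering to its set point from a small tissue.
kind = "simulate"
seed = 0

[circuit]
preset = "monophasic"

[initial]
Z = 1.0
y = 4.0

[run]
horizon = 200.0
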