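# Started far below the basin of attraction the biphasic tissue cannot
# recover: mass decays to zero while the uncleared signal runs away.
kind = "simulate"
seed = 0

[circuit]
preset = "biphasic"

[initial]
Z = 0.05
y = 4.06

[run]
horizon = 200.0
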