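# Poisson mutation schedule against the biphasic toy circuit: strong
# loss-of-function and locked-on clones dominate the arrivals and are
# each eliminated by the biphasic toxicity.
kind = "invade"
seed = 7

[circuit]
preset = "biphasic"

[initial]
Z = 6.16
y = 4.06

[run]
horizon = 300.0

[schedule.stochastic]
rate = 0.02
horizon = 300.0
seed = 7
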