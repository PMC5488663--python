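# Conditional knock-in of a six-fold activating GCK mutant in 25% of the
# beta-cell mass: glucose dips, the mutants are purged over ~3 weeks.
kind = "betacell"
seed = 0

[model]
fraction = 0.25
fold = 6.0
days = 60.0
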