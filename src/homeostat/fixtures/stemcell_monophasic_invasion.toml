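# Sensing-dead stem-cell mutant (senses y/16) under monophasic renewal
# control: it always sees "too little tissue" and expands without bound.
kind = "stemcell"
seed = 0

[initial]
Z_s = 0.5
Z_s_mut = 0.0
Z_d = 1.0

[model]
law = "monophasic"
mutant_time = 10.0
mutant_mass = 0.01
fold = 0.0625
horizon = 60.0
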