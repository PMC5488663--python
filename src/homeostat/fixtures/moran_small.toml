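# Small Moran compartment used as the stochastic oracle for the
# closed-form fixation probability.
kind = "moran"
seed = 0

[model]
N = 50
fitness = 3.0
mutation_rate = 0.0
initial_mutants = 1
max_generations = 10000
replicates = 2000
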