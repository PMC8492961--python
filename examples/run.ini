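# End-to-end synthetic study: generate a condition pair, normalize, build a
# Latin-hypercube library, fit both conditions, compare metrics, and compute
# nucleosome statistics. All stages are deterministic given the seed.
[run]
seed = 0
n_genes = 120
n_sets = 48
population = 300
k_best = 10

[stages]
synth = true
normalize = true
metagene = true
fit = true
compare = true
dyads = true
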