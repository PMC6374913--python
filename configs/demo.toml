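# Demo run: four species, 300 orthogroups, three replicates per generation.
# genbias run --config configs/demo.toml --outdir scratch/demo --seed 1

[simulate]
n_orthogroups = 300
seed = 1

[traitmap]
n_maps = 1000
seed = 1
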