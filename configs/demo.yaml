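# Default end-to-end demo: simulate the toy genome (HML/HMR-like loci,
# telomere-like ends, control region), aggregate and smooth the methylation
# track, and call a spread boundary at every silencer / X-element anchor.
seed: 11
outdir: scratch/demo
stages: [simulate, aggregate, infer]

# simulation
coverage: 30
mean_read_length: 8000
adenine_density: 0.31
nucleosome_repeat: 165
peak_occupancy: 0.9
decay_length: 2500
boundary_attenuation: 0.0
background_occupancy: 0.005
methylation_rate: 0.8
tpr: 0.9
fpr: 0.01

# processing
threshold: 0.8
min_coverage: 10
enp_target: 100
merge_strands: true

# inference
background_k: 2.0
run_length: 300
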