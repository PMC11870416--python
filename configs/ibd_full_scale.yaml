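# Full-scale individual-based simulation configuration (cluster use).
# Desk-scale defaults in argspace.IBDParams are a reduced version of this.
# Run:  argspace simulate ibd --config configs/ibd_full_scale.yaml --seed 1 --out out/sim
n0: 10000
area: [100.0, 100.0]
sigma_d2: 0.25
sigma_m2: 0.25
sigma_c2: 0.25
generations: 2000
sequence_length: 1.0e6
recomb_rate: 1.0e-8
num_samples: 500
cutoff: 2000.0
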