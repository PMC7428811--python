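# Study constants: species masses/lifespans, human tissue stem-cell
# compartments, metabolic-rate scaling exponents, and the 1% lifetime
# risk target anchoring the hypothetical-mouse baselines.
species:
  - {name: mouse, weight: 0.02, lifespan: 2}
  - {name: human, weight: 60, lifespan: 80}
  - {name: blue_whale, weight: 150000, lifespan: 90}
baseline_species: mouse
reference_species: human
target_species: [human, blue_whale]
tissues:
  - {name: colorectal, C_ref: 2.0e+8, k_ref: 73}
  - {name: hepatocellular, C_ref: 3.01e+8, k_ref: 0.9125}
  - {name: esophageal, C_ref: 6.6528e+6, k_ref: 33.2}
betas: [0.0, -0.15, -0.3]
p_target: 0.01
u_anchor: 1.0e-5
M_max: 10
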