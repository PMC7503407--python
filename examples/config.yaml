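# Example run configuration. Every section is optional; omitted keys use
# the package defaults (the standard networking parameters and the
# Trp-containing APT study constraints).

output_dir: aptnet_out

network:
  min_cosine: 0.65
  mutual_rank_k: 10
  fragment_tol_da: 0.025
  parent_mass_tol_da: 0.1

simulation:
  seed: 1
  ppm_sigma: 2.0
  replicates_per_compound: 3
  n_background: 20

constraints:
  X1: [Val, Leu]
  X2: [Lys]
  X3: [Val, Ile, Leu]
  X4: [Trp]
  X5: [MeAla]
  X6: [Phe]

annotation_tol_ppm: 10.0
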