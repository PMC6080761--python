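# Default run configuration: direct proton transfer, Path 1 energetics.
# Protocol constants follow the published umbrella-sampling setup:
# k = 150 kcal/mol/Å², window step 0.1 Å over ±1.7 Å (35 windows),
# D_ref,0 = -1.2 Å for an amino-acid acceptor (-1.0 Å for water).
surface:
  kind: direct
  reaction_energy: 17.6
  barrier_height: 18.7
  reactant_position: -1.2
  product_position: 1.2
protocol:
  acceptor_kind: amino_acid
  force_constant: 150.0
  window_equil_sweeps: 25000
  prod_sweeps: 25000
  proposal_sigma: 0.05
wham:
  bin_width: 0.05
  tolerance: 1.0e-7
  max_iterations: 100000
analysis:
  hbond_distance_cutoff: 3.5
  hbond_angle_cutoff: 140.0
  analysis_span_fraction: 0.5
  smoothing_window: 101
report:
  path_id: 1
  metadata:
    proton_transfer: direct
    final_acceptor: E162
    monomer: 1
    e162_protonated: "-"
seed: 2024
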