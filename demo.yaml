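# Demo pipeline configuration: synthetic five-substrate incubation with
# three DOM-release arms. Run with: domfinger run --config demo.yaml
seed: 42
output_dir: scratch/demo_run
simulate:
  n_formulas: 600
  treatments: [glucose, laminarin, syn_dom, oligo_dom, eu_dom]
  timepoints: [0, 4, 60]
  replicates: 3
  arms: [exudate, mechanical, viral]
  mass_error_ppm_sd: 0.3
  intensity_noise_cv: 0.3
  eem_snr: 20
assignment:
  tolerance_ppm: 1.0
  match_library_bounds: true
rank:
  coverage_threshold: 0.8
stats:
  n_permutations: 999
  alpha: 0.05
parafac:
  n_components: 4
  n_restarts: 2
  max_iter: 600
  tol: 1.0e-11
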