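# Small synthetic end-to-end run (finishes in about a minute).
out_dir: scfc_synthetic_run
seed: 7
n_regions: 50
n_mz_pairs: 25
n_dz_pairs: 13
n_full_sibs: 98
n_singletons: 26
n_fc_measurements: 4
coupling_mean: 0.25
coupling_sd: 0.08
sc_density: 0.35
n_perm: 500
alpha: 0.05
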