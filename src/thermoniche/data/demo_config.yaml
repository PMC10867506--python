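# Packaged two-species demo: synthetic tags, fitted lake-trout ED model
# (piecewise, breakpoint recovered from synthetic lipid data), packaged
# single-segment Chinook ED model.
seed: 0
make_plots: true
runs:
  - species: lake_trout
    ed_source: fit
    lipid_n: 1200
    lipid_noise_sd: 1.0
    ed_iterations: 200
    ed_alpha: 0.001
  - species: chinook_salmon
    ed_source: default
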