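prey,proportion,energy_density_J_g,indigestible_fraction
alewife,0.62,6536,0.033
round_goby,0.18,4180,0.033
rainbow_smelt,0.13,4800,0.033
sculpins,0.04,4500,0.033
other,0.03,5000,0.033
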