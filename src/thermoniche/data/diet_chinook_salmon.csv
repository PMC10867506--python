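prey,proportion,energy_density_J_g,indigestible_fraction
alewife,0.96,6536,0.033
rainbow_smelt,0.03,4800,0.033
other,0.01,5000,0.033
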