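# Lake trout (Salvelinus namaycush) physiological parameters, transcribed from
# the Fish Bioenergetics 4.0 defaults (Deslauriers et al. 2017), which carry the
# original values of Stewart, Weininger, Rottiers & Edsall (1983, CJFAS 40).
# Consumption: exponential temperature dependence (CEQ 1).
# Respiration: exponential with swimming-speed activity multiplier (REQ 1).
# Waste: Elliott-type temperature/ration-dependent egestion with indigestible
# prey correction (FEQ 3) and matching excretion (UEQ 3).
name: lake trout
consumption:
  CA: 0.0589
  CB: -0.307
  CEQ: 1
  CQ: 0.1225
respiration:
  RA: 0.00463
  RB: -0.295
  REQ: 1
  RQ: 0.059
  RTO: 0.0232
  RTM: 0.0
  RTL: 11.0
  RK1: 1.0
  RK4: 0.05
  ACT: 11.7
  BACT: 0.0405
  SDA: 0.172
waste:
  FEQ: 3
  UEQ: 3
  FA: 0.212
  FB: -0.222
  FG: 0.631
  UA: 0.0314
  UB: 0.58
  UG: -0.299
oxycal: 13560.0
optimum_temp: 10.0        # lab-derived physiological optimum, deg C
sim_start: [4, 1]         # simulation year starts April 1
start_weight: 142.0       # g at first simulated age
age_span: [1, 15]         # simulate from age 1 through age 15
age_specific_endpoints: [6573.0, 6980.0]  # age 13 -> 14 weights, g
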