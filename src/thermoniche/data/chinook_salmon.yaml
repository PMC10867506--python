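# Chinook salmon (Oncorhynchus tshawytscha) physiological parameters,
# transcribed from the Fish Bioenergetics 4.0 defaults (Deslauriers et al.
# 2017), which carry the original values of Stewart & Ibarra (1991, CJFAS 48).
# Consumption: Thornton-Lessem double sigmoid (CEQ 3).
# Respiration: exponential with swimming-speed activity multiplier (REQ 1).
# Waste: Elliott-type egestion/excretion (FEQ 3 / UEQ 3).
name: chinook salmon
consumption:
  CA: 0.303
  CB: -0.275
  CEQ: 3
  CQ: 5.0
  CTO: 15.0
  CTM: 18.0
  CTL: 24.0
  CK1: 0.36
  CK4: 0.01
respiration:
  RA: 0.00264
  RB: -0.217
  REQ: 1
  RQ: 0.06818
  RTO: 0.0234
  RTM: 0.0
  RTL: 25.0
  RK1: 1.0
  RK4: 0.13
  ACT: 9.7
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
optimum_temp: 14.3        # lab-derived physiological optimum, deg C
sim_start: [9, 1]         # simulation year starts September 1
start_weight: 200.0       # g at first simulated age
age_span: [0, 4]          # simulate from age 0 through age 4
age_specific_endpoints: [9742.0, 10387.0]  # age 3 -> 4 weights, g
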