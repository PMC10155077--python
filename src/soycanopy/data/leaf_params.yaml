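# Leaf photosynthesis parameter set (C3 soybean defaults).
# All 25-degree values are at a leaf temperature of 25 C.
vcmax25: 110.0        # umol m-2 s-1, maximum Rubisco carboxylation rate
jmax25: 195.0         # umol m-2 s-1, maximum electron transport rate
rd25: null            # umol m-2 s-1, dark respiration; null -> 0.015 * vcmax25
tpu25: 23.0           # umol m-2 s-1, triose-phosphate utilization capacity
theta: 0.7            # curvature of the non-rectangular hyperbola light response
leaf_absorb: 0.85     # leaf absorptance of incident PPFD
f_spectral: 0.15      # spectral/photosystem loss fraction of absorbed light
kc25: 405.0           # umol mol-1, Michaelis constant for CO2
ko25: 278.0           # mmol mol-1, Michaelis constant for O2
gamma_star25: 42.75   # umol mol-1, CO2 compensation point without Rd
o2: 210.0             # mmol mol-1, ambient O2 mole fraction
bb_slope: 9.0         # Ball-Berry slope (dimensionless)
bb_intercept: 0.01    # mol m-2 s-1, Ball-Berry intercept (residual conductance)
# Arrhenius activation energies, J mol-1
ha_vcmax: 65330.0
ha_jmax: 43540.0
ha_rd: 46390.0
ha_tpu: 53100.0
ha_kc: 79430.0
ha_ko: 36380.0
ha_gamma_star: 37830.0
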