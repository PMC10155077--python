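# Soybean canopy architecture, site, and growth configuration.
site:
  latitude: 40.04          # degrees N (central Illinois)

canopy:
  n_layers: 10
  k_diffuse: 0.7           # diffuse extinction coefficient
  scatter: 0.2             # leaf scattering coefficient
  k_nitrogen: 0.05         # photosynthetic-capacity extinction per unit LAI depth
  min_cos_zenith: 0.05     # floor on cos(zenith) for beam extinction
  albedo: 0.23             # canopy shortwave albedo
  ppfd_to_sw: 0.4376       # W m-2 of total shortwave per umol m-2 s-1 PPFD
  canopy_height_m: 1.0     # for the aerodynamic-conductance roughness rule
  ref_height_m: 3.0
  min_wind_m_s: 0.5

growth:
  t_base: 10.0             # C, base temperature for thermal time
  sowing_doy: 152
  end_doy: 280            # hard end of season (frost/harvest cutoff)
  tt_emerge: 60.0          # C d, sowing -> canopy growth start
  tt_repro: 750.0          # C d, vegetative -> reproductive transition
  tt_senesce: 1000.0       # C d, onset of leaf senescence
  tt_mature: 1450.0        # C d, physiological maturity
  sla_lai_per_mg_ha: 2.0   # LAI per Mg/ha of green leaf biomass
  growth_efficiency: 0.7   # fraction of positive net C retained after growth respiration
  labile_cap_mg_ha: 0.3    # Mg/ha ceiling of the labile carbohydrate pool
  senescence_rate_per_cd: 0.003   # fraction of green leaf lost per C d past onset
  init_leaf_mg_ha: 0.04
  init_stem_mg_ha: 0.02
  init_root_mg_ha: 0.02
  init_labile_mg_ha: 0.10

# Logistic carbon-partitioning weights vs thermal time (C d).
# weight_i(tt) = amplitude / (1 + exp((tt - center) / width)); pod uses a
# rising logistic and is hard-gated to zero before tt_repro.
partition:
  leaf:  {amplitude: 0.40, center: 900.0,  width: 120.0}
  stem:  {amplitude: 0.40, center: 1000.0, width: 120.0}
  root:  {amplitude: 0.15, center: 800.0,  width: 150.0}
  pod:   {amplitude: 0.80, center: 1050.0, width: 90.0}
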