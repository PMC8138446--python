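# Default liver-chip configuration: every value is the as-published one.
geometry:
  chamber_length_um: 5560.0
  chamber_width_um: 560.0
  cell_chamber_height_um: 100.0
  media_channel_height_um: 100.0
  membrane_thickness_um: 15.0
  membrane_porosity: 0.056
  membrane_pore_diameter_um: 3.0
  pdms_slab_thickness_mm: 3.5
transport:
  flow_rate_ul_per_h: 20.0
  fluid_density_kg_m3: 1000.0
  dynamic_viscosity_mpa_s: 0.78
  d_o2_media: 3.0e-9
  d_o2_pdms: 3.25e-9
  d_small_molecule: 1.0e-9
  c_inlet_o2: 0.173
  c_sat_pdms_mm: 1.11
  vo2max: 1.04e-16
  km_mmhg: 5.6
  s_cell_mm_per_atm: 1.049
  rho_cell: 6.44e+13
  n_cells: 9812
  ambient_o2_fraction: 0.187
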