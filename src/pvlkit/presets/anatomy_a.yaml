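case_id: A
bpm: 70
pressure:
  dp_sys_avg_mmhg: 29.7
  dp_dia_avg_mmhg: -86.6
  systole_s: 0.21
  transition_s: 0.03
targets:
  eoa_cm2: 1.5
  leak_ml_per_beat: 12.7
  closing_ml_per_beat: 3.7
geometry:
  lvot_radius_m: 0.01
  orifice_radius_m: 0.007
  sinus_length_m: 0.02
  seeding_plane_z_m: -0.02
  inlet_z_m: -0.04
  outlet_margin_m: 0.03
  channels:
  - azimuth_deg: 0
    width_m: 0.00772
    height_m: 0.0005
  - azimuth_deg: 180
    width_m: 0.00772
    height_m: 0.0005
schedule:
  ramp_s: 0.01
  closing_tau_s: 0.015
  r_valve_closed: 10000.0
seeding:
  spacing_m: 0.0002
  cadence_s: 0.0005
  window_s: 0.21
  window_start_cycles: 2
integrator:
  dt_s: 0.0005
  export_every: 2
  n_cycles: 3
  mode: tracer
field:
  wash_frac: 0.08
  feed_frac: 0.1
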