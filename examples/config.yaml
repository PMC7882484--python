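# Default study configuration: reference arena/plume/policy/likelihood
# constants. Edit a copy and pass it via --config.
analysis:
  alpha: 0.05
  cum_hits_edges:
  - 0.0
  - 10.0
  - 25.0
  - 50.0
  - 100.0
  - 200.0
  - 400.0
  histogram_bins: 50
  hit_rate_edges:
  - 0.0
  - 1.0
  - 2.0
  - 4.0
  - 8.0
  - 16.0
  hit_rate_window: 1.0
  rmse_window: 20
arena:
  goal_radius: 35.0
  heading_frame: upwind
  length_x: 350.0
  sample_rate: 20.0
  source_pos:
  - 0.0
  - 0.0
  start_pose:
  - 180.0
  - 0.0
  - -0.5235987755982988
  time_limit: 180.0
  width_y: 200.0
  wind_angle: 0.0
  wind_speed: 0.1
classify:
  min_speed: 0.0
  rotate_blank_min: 0.2
  slow_omega_max: 5.0
  surge_blank_max: 0.5
likelihood:
  agent_radius: 10.0
  cell_size: 5.0
  diffusivity: 2000.0
  emission_rate: 1.0
  particle_lifetime: 3.0
  wind_angle: 0.0
  wind_speed: 100.0
plume:
  emission_rate: 10.0
  growth_rate: 12.0
  initial_radius: 10.0
  lateral_meander_sd: 30.0
  lifetime: 4.0
policy:
  antenna_offset: 3.0
  deviation_omega_max: 180.0
  deviation_omega_min: 30.0
  deviation_rate: 0.0
  loop_speed: 12.0
  loop_turn_rate: 60.0
  surge_duration: 0.5
  surge_speed: 24.0
  zigzag_leg_duration: 2.0
  zigzag_phase_duration: 6.0
  zigzag_speed: 12.0
  zigzag_turn_rate: 90.0
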