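# Default run configuration.  Every key here can be overridden from a user
# config file; unknown keys are rejected.
anatomy:
  domain_width: 0.300
  domain_height: 0.250
  cord_semiaxes: [0.005, 0.004]
  csf_annulus_thickness: 0.0025
  dura_thickness: 0.001
  epidural_thickness: 0.003
  yellow_ligament_thickness: 0.004
  vertebral_body_semiaxes: [0.022, 0.015]
  posterior_arch_thickness: 0.008
  subcutaneous_thickness: 0.010
  viscera_center: [0.0, -0.060]
  viscera_semiaxes: [0.100, 0.042]
  catheter_outer_radius: 0.0015
  catheter_lumen_radius: 0.0010
  catheter_dorsal_offset: 0.0015
  torso_margin: 0.002
  torso_corner_radius: 0.040

blood:
  specific_heat: 3617.0
  density: 1050.0
  arterial_temperature: 36.15

solver:
  # spacing/dt left null take the fidelity preset values
  # (desk: 1 mm / 0.5 s; paper: 0.5 mm / 0.02 s)
  fidelity: desk
  spacing: null
  dt: null
  stationary_tol: 1.0e-10

calibration:
  skin_model: power_law          # power_law | constant
  skin_convection_coefficient: 2.0   # C in h = C dT^exponent
  skin_convection_exponent: 0.25
  ambient_temperature: 30.0
  csf_conductivity_factor: 1.0   # effective-conductivity surrogate for CSF mixing
  extra_density_factor: false    # sensitivity variant of the perfusion term

protocol:
  coolant_setpoint: 20.0         # degC; sweep covers 20, 16, 12, 8
  cooling_duration: 1800.0       # s
  stoppage_duration: 1800.0      # s
  report_interval: 10.0          # s
  snapshot_times: []

output:
  directory: runs
  formats: [csv, vtk]
  render_range: [18.0, 38.0]
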