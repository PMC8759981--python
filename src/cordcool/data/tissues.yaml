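# Thermophysical tissue registry for the axial spinal-cord cross-section.
#
# density              kg/m^3
# thermal_conductivity W/(m K)
# specific_heat        J/(kg K)
# metabolic_heat       W/m^3          (volumetric metabolic source q_m)
# perfusion_mass_rate  kg/(s m^3)     (blood mass perfusion w_b; the
#                                      perfusion source is w_b c_b (Ta - T))
# viscosity            Pa s           (stored for completeness; unused by the
#                                      conduction solver)
#
# The catheter is inert (no metabolism, no perfusion); cerebrospinal fluid is
# avascular and carries no metabolic load.
tissues:
  cerebrospinal_fluid:
    density: 1100.0
    thermal_conductivity: 0.57093
    specific_heat: 1000.0
    metabolic_heat: 0.0
    perfusion_mass_rate: 0.0
    viscosity: 0.001
  spinal_cord:
    density: 1075.0
    thermal_conductivity: 0.51
    specific_heat: 3630.0
    metabolic_heat: 2666.0
    perfusion_mass_rate: 3.01
  dura:
    density: 1174.0
    thermal_conductivity: 0.44
    specific_heat: 3364.0
    metabolic_heat: 6914.86
    perfusion_mass_rate: 7.80710
  epidural_space:
    density: 911.0
    thermal_conductivity: 0.21
    specific_heat: 2348.0
    metabolic_heat: 464.61
    perfusion_mass_rate: 0.52610
  yellow_ligament:
    density: 1142.0
    thermal_conductivity: 0.47
    specific_heat: 3432.0
    metabolic_heat: 513.9
    perfusion_mass_rate: 0.57957
  spine:
    density: 1178.0
    thermal_conductivity: 2.2093
    specific_heat: 1313.0
    metabolic_heat: 176.7
    perfusion_mass_rate: 0.20615
  muscle:
    density: 900.0
    thermal_conductivity: 0.49
    specific_heat: 3421.0
    metabolic_heat: 864.0
    perfusion_mass_rate: 0.61425
  splanchnic_tissue:
    density: 737.0
    thermal_conductivity: 0.465
    specific_heat: 3749.5
    metabolic_heat: 14668.51
    perfusion_mass_rate: 10.48333
  subcutaneous_tissue:
    density: 1009.5
    thermal_conductivity: 0.29
    specific_heat: 2869.5
    metabolic_heat: 1146.98
    perfusion_mass_rate: 1.29136
  catheter:
    density: 900.0
    thermal_conductivity: 0.3349
    specific_heat: 550.0
    metabolic_heat: 0.0
    perfusion_mass_rate: 0.0

blood:
  specific_heat: 3617.0
  density: 1050.0
  # Arterial blood temperature. Calibrated so the no-cooling stationary
  # cord-center temperature sits at ~36.4 degC, the baseline the rewarming
  # curve approaches; see docs/methods.md.
  arterial_temperature: 36.15
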