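# Beam-quality correction factors k_Q for the nanoDot OSLD on a GE Discovery
# CT750 HD (medium bowtie filter), relative to each calibration protocol.
# These values are scanner-spectrum dependent: scanners with a softer
# spectrum (e.g. some Toshiba models) need their own table, which is why the
# values ship as versioned data rather than constants in code.
version: 1
scanner: "GE Discovery CT750 HD, medium bowtie filter"

# k_Q indexed by the mean spectral energy at the dosimeter position
# (from Monte Carlo simulation of the measurement condition).
k_q_by_energy:
  - {condition: 1, kvp: 80, energy_keV: 45.4, ct_air: 0.82, megavoltage: 0.29}
  - {condition: 2, kvp: 80, energy_keV: 47.9, ct_air: 0.85, megavoltage: 0.30}
  - {condition: 3, kvp: 120, energy_keV: 51.7, ct_air: 0.88, megavoltage: 0.31}
  - {condition: 4, kvp: 120, energy_keV: 54.7, ct_air: 0.91, megavoltage: 0.33}
  - {condition: 5, kvp: 120, energy_keV: 55.3, ct_air: 0.93, megavoltage: 0.33}
  - {condition: 6, kvp: 140, energy_keV: 58.1, ct_air: 0.97, megavoltage: 0.35}
  - {condition: 7, kvp: 140, energy_keV: 58.7, ct_air: 0.96, megavoltage: 0.34}
  - {condition: 8, kvp: 120, energy_keV: 59.5, ct_air: 1.00, megavoltage: 0.36}
  - {condition: 9, kvp: 120, energy_keV: 60.7, ct_air: 1.02, megavoltage: 0.36}
  - {condition: 10, kvp: 140, energy_keV: 63.2, ct_air: 1.06, megavoltage: 0.38}
  - {condition: 11, kvp: 140, energy_keV: 64.9, ct_air: 1.09, megavoltage: 0.39}

# Clinical simplification: k_Q by nominal kVp and measurement position,
# averaged over phantom sizes and scan extents.  "periphery" means the
# 1 cm depth bore of the CTDI phantom.
k_q_by_kvp_position:
  ct_air:
    80: {surface: 0.85, periphery: 0.83, center: 0.81}
    120: {surface: 1.03, periphery: 0.98, center: 0.90}
    140: {surface: 1.10, periphery: 1.03, center: 0.94}
  megavoltage:
    80: {surface: 0.30, periphery: 0.30, center: 0.29}
    120: {surface: 0.37, periphery: 0.35, center: 0.33}
    140: {surface: 0.39, periphery: 0.37, center: 0.34}

# The reader vendor prescribes a single energy correction for all CT
# measurements, regardless of spectrum.
vendor_k_q: 1.19

# Irradiation-geometry correction: rotating CT delivery versus the static
# en-face irradiation used for megavoltage calibration standards.
k_g:
  vendor: 1.0
  ct_air: 1.0
  megavoltage: 1.03

# Relative 2-sigma uncertainties (percent) attached to looked-up factors.
# The k_Q entries are chosen so that the total propagated dose uncertainty
# reflects the overall precision reported for each protocol (roughly 13.5%,
# 8.3% and 8.5% at 2 sigma); they are configuration, not measurements, and
# should be replaced when protocol-specific estimates are available.
uncertainty_rel_2sigma_pct:
  k_q: {vendor: 12.4, ct_air: 6.3, megavoltage: 8.2}
  k_g: {vendor: 0.0, ct_air: 0.0, megavoltage: 1.0}
  k_l: 0.0
  k_f: 0.0
  k_theta: 0.0
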