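"""Physical constants and measured default coefficients used across modules.

Units throughout the package: lengths in micrometers, forces in nanonewtons,
pressures in millibar, membrane tension in mN/m (identical to nN/um), and
fluorescence lifetimes in nanoseconds.
"""

# 1 mbar = 100 Pa = 100 nN/mm^2 = 1e-4 nN/um^2 * 1e3 ... worked out:
# 100 Pa = 100 N/m^2 = 100 * 1e-9/1e-12 nN/um^2 * 1e-3 = 0.1 nN/um^2
MBAR_TO_NN_PER_UM2 = 0.1

# Measured linear coefficients converting a mechanical stimulus into a mean
# local membrane tension change (used as generator/demo defaults).
DEFAULT_ALPHA_F = 0.0065  # (mN/m) per nN of indentation force
DEFAULT_ALPHA_P = 0.0024  # (mN/m) per mbar of aspiration pressure
DEFAULT_ALPHA_F_AREA = 0.0076  # (mN/m)*um^2 per nN
DEFAULT_ALPHA_P_AREA = 0.0325  # (mN/m)*um^2 per mbar

# Lifetime-to-tension conversion factor for the flipper probe, from the
# osmotic-shock tether-pulling calibration.
DEFAULT_CONVERSION_FACTOR = 1.325  # (mN/m) per ns

# Measured calcium wave-front propagation speed, used as the generator default.
DEFAULT_WAVE_SPEED_UM_S = 22.4

# Stepped-aspiration protocol parameters.
DEFAULT_PRESSURE_STEP_MBAR = 25.0
DEFAULT_PRESSURE_MAX_MBAR = 400.0

# Minimum photon budgets for a statistically meaningful lifetime fit.
MIN_PHOTONS_PER_PIXEL = 1000
MIN_PHOTONS_PER_KYMO_PIXEL = 500
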