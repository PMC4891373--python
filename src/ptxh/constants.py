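"""Physical constants and scanner defaults used across the package."""

#: Reduced gyromagnetic ratio of 1H, gamma-bar, in Hz/T.
GAMMA_BAR_HZ_PER_T = 42.577478461e6

#: Proton Larmor frequency at 9.4 T, in Hz (used for Hz <-> ppm conversion).
F0_9T4_HZ = 400.2e6

#: Head-gradient hardware limits.
G_MAX_T_PER_M = 0.080
SLEW_MAX_T_PER_M_PER_S = 333.0

#: Per-channel RF amplifier peak voltage (1 kW into 50 Ohm).
PEAK_VOLTAGE_V = 179.0

#: CP-mode transmit efficiency used as the default phantom scale, in uT per
#: volt of common drive (10 uT nominal peak B1 at 79.8 V per channel).
CP_MODE_UT_PER_V = 10.0 / 79.8

#: Spherical-harmonic reference radius for shim-coil calibration, in mm.
SH_REFERENCE_RADIUS_MM = 100.0
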