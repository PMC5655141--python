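"""Physical constants and field conventions shared across the package."""

#: Ideal gas constant in kcal mol^-1 K^-1 (the unit system of calorimetry tables).
R_KCAL: float = 1.987e-3

#: Default absolute temperature (K) for state-function derivations.
T_STANDARD: float = 298.0

#: Gyromagnetic ratio of 13C relative to 1H; sets the 13C carrier frequency
#: for a spectrometer quoted by its 1H frequency (750 MHz 1H -> 188.6 MHz 13C).
CARBON_FREQ_RATIO: float = 0.251449530

#: Default spectrometer 1H frequency in MHz.
H_FREQ_MHZ: float = 750.0

#: Corresponding 13C frequency in MHz.
C_FREQ_MHZ: float = H_FREQ_MHZ * CARBON_FREQ_RATIO

#: Conventional 13C scaling weight in combined methyl chemical-shift perturbations.
DEFAULT_CARBON_WEIGHT: float = 0.25
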