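# Pepper weevil (Anthonomus eugenii) ecoclimatic response parameters.
# Temperatures in deg C; soil moisture as fraction of capacity; stress
# rates per week (negative signs mark direction, magnitudes are used);
# PDD in degree-days above DV0. Diapause is not set for this species.

DV0 = 9.6     # lower temperature threshold
DV1 = 28     # lower optimum temperature
DV2 = 31     # upper optimum temperature
DV3 = 33     # upper temperature threshold

SM0 = 0.1    # lower soil moisture threshold
SM1 = 0.7    # lower optimal soil moisture
SM2 = 0.85   # upper optimal soil moisture
SM3 = 1.5    # upper soil moisture threshold

TTCS = -10   # cold stress temperature threshold
THCS = -0.01 # cold stress accumulation rate (week^-1)
TTHS = 41.7  # heat stress temperature threshold
THHS = 0.005 # heat stress accumulation rate (week^-1)

SMDS = 0.1   # dry stress threshold
HDS = -0.005 # dry stress rate (week^-1)
SMWS = 2     # wet stress threshold
HWS = 0.001  # wet stress rate (week^-1)

PDD = 256.4  # degree-days to complete one generation
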