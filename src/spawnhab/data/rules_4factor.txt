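# Fuzzy rules of the four-factor spawning-habitat model for C. guichenoti.
# Columns: substrate temperature velocity depth HSI
# Tokens: VL L M H VH, "/" = or, AC = entire fuzzy set of the factor.
L/M/H  M      L/H    L/H    M
L/M/H  L/H    M      L/H    M
M      L/H    L/H    M      M
L/H    L/H    L/H    M      L
L/M/H  M      M      L/H    H
L/M/H  M      L/H    M      H
M      L/H    M      M      H
L/H    L/H    M      M      M
L/M/H  M      M      M      VH
VL     AC     AC     AC     L
L/M/H  VL/VH  AC     AC     L
L/M/H  L/M/H  VL/VH  AC     L
L/M/H  L/M/H  L/M/H  VL/VH  L
# Boulder-dominated beds depress spawning suitability; mirrors the sand
# (substrate VL) blocking row above.
VH     AC     AC     AC     L
# Completion row: every factor within range but only marginally suitable.
# Keeps the rule base complete over all grade combinations.
L/M/H  L/H    L/H    L/H    L
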