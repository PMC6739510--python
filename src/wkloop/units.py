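"""Unit conversions between the user-facing convention and internal SI.

Internally everything is strict SI: N, m, Pa, m^3, s, Pa·s·m^-3, m^3·Pa^-1.
Configuration files and the CLI use the conventions of the cardiac-mechanics
literature (mN, mm, kPa, GPa·s·m^-3, pm^3·Pa^-1, µL/s); conversion happens
only at that boundary.
"""

# multiply a value in the named unit by the constant to obtain SI
MN = 1e-3               # millinewton -> N
MM = 1e-3               # millimetre -> m
KPA = 1e3               # kilopascal -> Pa
GPA_S_PER_M3 = 1e9      # GPa·s·m^-3 -> Pa·s·m^-3
PM3_PER_PA = 1e-12      # pm^3·Pa^-1 -> m^3·Pa^-1  ("p" = pico on the m^3)
UL = 1e-9               # microlitre -> m^3
UL_PER_S = 1e-9         # µL/s -> m^3/s
MM3 = 1e-9              # mm^3 -> m^3
US = 1e-6               # microsecond -> s
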