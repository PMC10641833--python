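"""Unit conventions and conversion constants.

Internal units everywhere in this package:

* length      — Å (ångström)
* time        — ps
* pressure    — bar
* tension     — mN/m
* diffusivity — 1e-9 cm²/s

All conversions between these live here so a unit error is a one-line fix.
"""

#: 1 bar·Å expressed in mN/m (1 bar·Å = 1e5 Pa · 1e-10 m = 1e-5 N/m).
BAR_ANGSTROM_TO_MN_PER_M: float = 0.01

#: 1 Å²/ps expressed in units of 1e-9 cm²/s (1 Å²/ps = 1e-4 cm²/s).
A2_PER_PS_TO_1E9_CM2_PER_S: float = 1.0e5

#: nm → Å, for readers whose native unit is nm (GRO/XTC).
NM_TO_ANGSTROM: float = 10.0
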