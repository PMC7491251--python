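"""Back-of-envelope geometry of periodic DNA structure.

A strictly sinusoidal arrangement with ~20 kbp loops is geometrically
implausible inside an E. coli cell: one such loop laid out as a circle is
already about as wide as the cell is long. These numbers motivate the
local-plectoneme (flower-like anchoring) picture instead.
"""

import math

from cpedscan import geometry

circ = geometry.contour_length_um(20_000)
diam = geometry.circle_diameter_um(20_000)
total = geometry.contour_length_mm(4.6e6)

print(f"20 kbp loop contour:       {circ:.1f} um")
print(f"20 kbp loop diameter:      {diam:.2f} um (~{math.floor(diam * 10) / 10})")
print(f"4.6 Mbp chromosome length: {total:.3f} mm (vs a ~2-3 um cell)")
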