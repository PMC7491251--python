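"""Back-of-envelope DNA contour geometry.

B-form DNA rises ~3.4 Angstrom per base pair, so a 20 kbp loop laid out as
a circle has a contour (circumference) of 6.8 um and a diameter of ~2.16 um
— comparable to the length of an E. coli cell, which is why a strictly
sinusoidal arrangement of ~20-40 kbp periodic structure is geometrically
implausible and local plectonemic anchoring is the more likely picture.
"""

from __future__ import annotations

import math

BP_RISE_ANGSTROM = 3.4

__all__ = ["contour_length_um", "contour_length_mm", "circle_diameter_um", "BP_RISE_ANGSTROM"]


def contour_length_um(n_bp: float, rise_angstrom: float = BP_RISE_ANGSTROM) -> float:
    """Contour length of ``n_bp`` base pairs of B-DNA, in micrometres."""
    return n_bp * rise_angstrom * 1e-4


def contour_length_mm(n_bp: float, rise_angstrom: float = BP_RISE_ANGSTROM) -> float:
    """Contour length in millimetres (a 4.6 Mbp chromosome is ~1.564 mm)."""
    return contour_length_um(n_bp, rise_angstrom) * 1e-3


def circle_diameter_um(n_bp: float, rise_angstrom: float = BP_RISE_ANGSTROM) -> float:
    """Diameter of a circle whose circumference is the contour of ``n_bp``."""
    return contour_length_um(n_bp, rise_angstrom) / math.pi
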