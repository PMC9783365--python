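"""Closed-form optical auxiliaries: depth from focus, magnification, USAF.

The depth-from-focus correction converts the stage travel ``t`` between
focusing on the surface and on a structure inside a medium of refractive
index ``n2`` (observed through air, ``n1 = 1``) into the structure depth:

    d = t * (n2 - sqrt(n2^2 - NA^2)) / (n1 - sqrt(n1^2 - NA^2))

with ``NA`` the numerical aperture of the objective. The formula is
implemented exactly as printed in the instrument's documentation lineage;
note that its small-NA limit is d -> t / n2, whereas the textbook paraxial
apparent-depth correction gives d = n2 * t — the ratio may be inverted
relative to the classical references. See docs/methods.md; the printed form
is kept deliberately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ValidationError


@dataclass(frozen=True)
class DepthMeasurement:
    """Stage travel between surface focus and structure focus, with optics.

    ``traverse_um``: nonnegative stage travel t; ``n1``: refractive index of
    the immersion medium (air, default 1); ``n2``: refractive index of the
    sample medium; ``NA``: numerical aperture, which must stay below both
    indices so the square roots are real.
    """

    traverse_um: float
    n2: float
    NA: float
    n1: float = 1.0

    def __post_init__(self):
        if self.traverse_um < 0:
            raise ValidationError("traverse_um must be nonnegative")
        if self.NA <= 0:
            raise ValidationError(
                "NA must be positive (the formula is 0/0 at NA = 0)"
            )
        if self.NA >= self.n1 or self.NA >= self.n2:
            raise ValidationError(
                f"NA ({self.NA}) must be smaller than both refractive "
                f"indices (n1={self.n1}, n2={self.n2})"
            )


def structure_depth(m: DepthMeasurement) -> float:
    """Depth of a structure below the surface from a focus traverse, μm."""
    numerator = m.n2 - math.sqrt(m.n2**2 - m.NA**2)
    denominator = m.n1 - math.sqrt(m.n1**2 - m.NA**2)
    return m.traverse_um * numerator / denominator


def system_magnification(
    nominal_mag: float,
    reference_tube_focal_mm: float = 200.0,
    tube_focal_mm: float = 150.0,
) -> float:
    """Overall magnification of an infinity-corrected objective + tube lens.

    An objective of nominal magnification M (specified for a reference tube
    focal length, 200 mm by Mitutoyo convention) used with a tube lens of
    focal length f yields ``M * f / f_reference``.
    """
    if nominal_mag <= 0 or reference_tube_focal_mm <= 0 or tube_focal_mm <= 0:
        raise ValidationError("all magnification arguments must be positive")
    return nominal_mag * tube_focal_mm / reference_tube_focal_mm


def usaf_linewidth_um(group: int, element: int) -> float:
    """Line width (μm) of a USAF-1951 resolution target element.

    Resolution in line pairs per mm is ``2^(group + (element - 1)/6)``; one
    line is half a line pair, so the width is ``500 / resolution`` μm.
    """
    if not 1 <= int(element) <= 6:
        raise ValidationError(f"element must be in 1..6, got {element}")
    resolution_lp_per_mm = 2.0 ** (group + (element - 1) / 6.0)
    return 500.0 / resolution_lp_per_mm
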