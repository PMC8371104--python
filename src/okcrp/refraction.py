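"""Thibos power-vector conversion of sphero-cylindrical refractions.

A refraction (S, C, axis) is decomposed into the spherical equivalent M
and the two Jackson crossed-cylinder components::

    M    = S + C/2
    J180 = -(C/2) cos(2 alpha)
    J45  = -(C/2) sin(2 alpha)

The decomposition is invariant under transposition of the
sphero-cylinder form, so plus-cylinder inputs are transposed to the
canonical minus-cylinder form on construction.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

__all__ = ["SpheroCylinder", "PowerVector", "to_power_vector", "delta_m"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpheroCylinder:
    """Sphero-cylindrical refraction, canonical minus-cylinder form.

    ``axis`` in degrees; inputs with axis in (0, 360] are folded into
    (0, 180] (the axis is 180-degree periodic) and plus-cylinder inputs
    are transposed, so equivalent forms compare equal.
    """

    sphere: float
    cylinder: float = 0.0
    axis: float = 180.0

    def __post_init__(self) -> None:
        if not (0.0 < self.axis <= 360.0):
            raise ValueError("axis must lie in (0, 360] degrees")
        sphere, cylinder, axis = self.sphere, self.cylinder, self.axis
        if cylinder > 0:  # transpose to minus-cylinder
            log.info("transposing plus-cylinder refraction to minus-cylinder form")
            sphere = sphere + cylinder
            cylinder = -cylinder
            axis = axis + 90.0
        axis = axis % 180.0
        if axis == 0.0:
            axis = 180.0
        object.__setattr__(self, "sphere", float(sphere))
        object.__setattr__(self, "cylinder", float(cylinder))
        object.__setattr__(self, "axis", float(axis))


@dataclass(frozen=True)
class PowerVector:
    """Thibos power vector (M, J180, J45), dioptres."""

    M: float
    J180: float
    J45: float

    @property
    def blur_strength(self) -> float:
        """Overall blur strength sqrt(M^2 + J180^2 + J45^2)."""
        return math.sqrt(self.M**2 + self.J180**2 + self.J45**2)


def to_power_vector(rx: SpheroCylinder) -> PowerVector:
    """Convert a sphero-cylindrical refraction to (M, J180, J45)."""
    half_c = rx.cylinder / 2.0
    two_alpha = math.radians(2.0 * rx.axis)
    return PowerVector(
        M=rx.sphere + half_c,
        J180=-half_c * math.cos(two_alpha),
        J45=-half_c * math.sin(two_alpha),
    )


def delta_m(baseline: PowerVector, post: PowerVector) -> float:
    """Change in spherical equivalent, post minus baseline (D)."""
    return post.M - baseline.M
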