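"""Independent numerical oracles used by the test-suite.

These deliberately avoid the package's closed-form code paths: the
power oracle traces an actual ray with vector Snell refraction and the
axial-radius oracle intersects a finite-difference surface normal with
the instrument axis.
"""
from __future__ import annotations

import numpy as np

from okcrp.synthetic import ConicSurface, conic_sag


def raytrace_power(x: float, z: float, r_a: float, n_prime: float = 1.3375) -> float:
    """Power from brute-force refraction of an axis-parallel ray.

    The incident ray travels along +z at height ``x`` and hits the
    surface at (x, z).  The surface normal points at the axial centre of
    curvature, on the axis at distance ``r_a`` from the point.  The ray
    is refracted with the vector form of Snell's law and followed to its
    crossing of the axis; power is n' over that axial distance (m).
    """
    zc = z + np.sqrt(r_a**2 - x**2)  # axial centre of curvature
    normal = np.array([-x, zc - z])
    normal /= np.linalg.norm(normal)
    d = np.array([0.0, 1.0])
    if np.dot(normal, d) > 0:
        normal = -normal
    cos_i = -np.dot(d, normal)
    eta = 1.0 / n_prime
    k = 1.0 - eta**2 * (1.0 - cos_i**2)
    t = eta * d + (eta * cos_i - np.sqrt(k)) * normal  # refracted direction
    s = -x / t[0]  # parameter at which the ray meets the axis
    z_cross_mm = z + s * t[1]
    return n_prime / (z_cross_mm / 1000.0)


def normal_intersection_radius(x: float, surface: ConicSurface,
                               h: float = 1e-5) -> float:
    """Axial radius by intersecting a finite-difference normal with the axis.

    Slope from a central difference of the sag; the normal line from
    (x, z) crosses the axis at distance x * sqrt(1 + p^2) / p.
    """
    p = float(conic_sag(x + h, surface) - conic_sag(x - h, surface)) / (2 * h)
    return x * np.sqrt(1 + p**2) / p
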