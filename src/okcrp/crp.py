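"""Corneal refractive power (CRP) along the principal meridians.

The power at radial distance ``x`` from the videokeratoscopic centre is
obtained by refracting an axis-parallel incident ray at the corneal
surface and locating the crossing of the refracted ray with the
instrument axis (Klein-Mandell construction)::

    P_R = n' / (z + x / tan(theta_i - theta_t))

with ``z`` the sagittal height at ``x``, ``theta_i = asin(x / r_a)`` the
incident angle (``r_a`` the axial radius of curvature) and
``sin(theta_t) = sin(theta_i) / n'`` the refracted angle under the
keratometric index ``n' = 1.3375``.  The denominator is the axial
intercept distance; lengths are carried in millimetres and converted to
metres so powers come out in dioptres.  At the apex the printed formula
is 0/0 and the analytic paraxial limit ``(n' - 1) / r_a`` is used.

Profiles are evaluated at fixed 0.5 mm offsets out to 4.0 mm on both
sides of the centre along the horizontal and vertical meridians, and
replicate maps of a visit are averaged per location.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .topo_io import TopographyGrid

__all__ = [
    "OpticalConstants",
    "MeridianProfile",
    "PROFILE_OFFSETS",
    "PROFILE_POSITIONS",
    "incident_angle",
    "refracted_angle",
    "crp_at",
    "interpolate_hemimeridian",
    "crp_profile",
    "average_maps",
]

log = logging.getLogger(__name__)

#: Unsigned hemi-meridian offsets (mm) at which CRP is evaluated.
PROFILE_OFFSETS = np.arange(1, 9) * 0.5
#: Signed meridian positions (mm): negative side (temporal/inferior)
#: first, ascending; the centre (0) is excluded.
PROFILE_POSITIONS = np.concatenate([-PROFILE_OFFSETS[::-1], PROFILE_OFFSETS])


@dataclass(frozen=True)
class OpticalConstants:
    """Optical constants of the single-surface corneal power model."""

    n_prime: float = 1.3375  # keratometric refractive index

    def __post_init__(self) -> None:
        if not self.n_prime > 1:
            raise ValueError("n_prime must exceed 1")


DEFAULT_CONSTANTS = OpticalConstants()


@dataclass
class MeridianProfile:
    """CRP sampled at the 16 fixed positions of one principal meridian.

    ``positions`` is always :data:`PROFILE_POSITIONS`; positive positions
    are nasal (horizontal) or superior (vertical).  Missing coverage is
    carried as NaN.  ``n_maps`` records, after averaging, how many maps
    contributed per position.
    """

    meridian: Literal["horizontal", "vertical"]
    positions: np.ndarray
    crp: np.ndarray
    n_maps: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.crp = np.asarray(self.crp, dtype=float)
        if not np.array_equal(self.positions, PROFILE_POSITIONS):
            raise ValueError("positions must be the fixed +/-0.5..4.0 mm grid")
        if self.crp.shape != self.positions.shape:
            raise ValueError("crp and positions shapes differ")


def incident_angle(x, r_a):
    """Incident angle theta_i = asin(x / r_a), radians.

    ``x`` is the radial distance and ``r_a`` the axial radius of
    curvature, both in mm.  Requires ``0 <= x <= r_a`` and ``r_a > 0``.
    """
    x = np.asarray(x, dtype=float)
    r_a = np.asarray(r_a, dtype=float)
    if np.any(r_a <= 0):
        raise ValueError("axial radius must be positive")
    if np.any(x < 0) or np.any(x > r_a):
        raise ValueError("radial distance must satisfy 0 <= x <= r_a")
    return np.arcsin(x / r_a)


def refracted_angle(theta_i, constants: OpticalConstants = DEFAULT_CONSTANTS):
    """Refracted angle from Snell's law: asin(sin(theta_i) / n')."""
    theta_i = np.asarray(theta_i, dtype=float)
    if np.any(theta_i < 0) or np.any(theta_i > np.pi / 2 + 1e-12):
        raise ValueError("incident angle must lie in [0, pi/2]")
    return np.arcsin(np.sin(theta_i) / constants.n_prime)


def crp_at(x, z, r_a, constants: OpticalConstants = DEFAULT_CONSTANTS):
    """Corneal refractive power (D) at radial distance ``x``.

    Parameters are in mm; the axial-intercept denominator is converted
    to metres before the division so the result is in dioptres.  At
    ``x = 0`` the analytic paraxial limit ``(n' - 1) / r_a`` is
    returned.  Scalar in, scalar out; arrays broadcast.

    Raises
    ------
    ValueError
        Outside the geometric domain (``x > r_a``, ``r_a <= 0``,
        negative sag) or when the axial intercept is non-positive
        (non-physical, non-convex geometry).
    """
    x, z, r_a = np.broadcast_arrays(
        np.asarray(x, dtype=float), np.asarray(z, dtype=float),
        np.asarray(r_a, dtype=float)
    )
    if np.any(z < 0):
        raise ValueError("sagittal height must be >= 0")
    theta_i = incident_angle(x, r_a)
    theta_t = refracted_angle(theta_i, constants)
    dev = theta_i - theta_t
    nonzero = x > 0
    if np.any(nonzero & (dev <= 0)):
        raise ValueError("theta_i == theta_t off axis: surface is flat at x > 0")
    denom_mm = np.empty_like(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom_mm[nonzero] = z[nonzero] + x[nonzero] / np.tan(dev[nonzero])
    if np.any(denom_mm[nonzero] <= 0):
        raise ValueError("non-positive axial intercept: non-physical geometry")
    out = np.empty_like(x)
    out[nonzero] = constants.n_prime / (denom_mm[nonzero] / 1000.0)
    out[~nonzero] = (constants.n_prime - 1.0) / (r_a[~nonzero] / 1000.0)
    if out.ndim == 0:
        return float(out)
    return out


def interpolate_hemimeridian(
    radial_mm: np.ndarray,
    values: np.ndarray,
    targets: np.ndarray,
    method: Literal["pchip", "linear"] = "pchip",
) -> np.ndarray:
    """Interpolate one hemi-meridian's samples at fixed radial offsets.

    Monotone shape-preserving piecewise-cubic (PCHIP) interpolation by
    default: it reproduces the sample knots exactly, is exact on linear
    data, and does not overshoot at the steep treatment-zone edge the
    way an ordinary cubic spline can.  Targets outside the sampled range
    are returned as NaN -- coverage is never extrapolated.  Fewer than
    two samples yields all-NaN.
    """
    radial_mm = np.asarray(radial_mm, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = np.asarray(targets, dtype=float)
    out = np.full(targets.shape, np.nan)
    if radial_mm.size < 2:
        return out
    if np.any(np.diff(radial_mm) <= 0):
        raise ValueError("radial_mm must be strictly increasing")
    inside = (targets >= radial_mm[0]) & (targets <= radial_mm[-1])
    if not np.any(inside):
        return out
    if method == "pchip":
        out[inside] = PchipInterpolator(radial_mm, values)(targets[inside])
    elif method == "linear":
        out[inside] = np.interp(targets[inside], radial_mm, values)
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    return out


def _nearest_meridian(grid: TopographyGrid, azimuth: float) -> int:
    """Index of the grid hemi-meridian nearest to ``azimuth`` (deg).

    Accepts the nearest meridian within half the angular spacing of the
    grid; raises if none qualifies (required hemi-meridian absent).
    """
    ang = grid.meridian_angles
    spacing = 360.0 / ang.size
    diff = np.abs((ang - azimuth + 180.0) % 360.0 - 180.0)
    idx = int(np.argmin(diff))
    if diff[idx] > spacing / 2.0 + 1e-9:
        raise ValueError(
            f"no hemi-meridian within {spacing / 2:g} deg of azimuth {azimuth:g} deg"
        )
    return idx


def _hemi_crp(
    grid: TopographyGrid,
    azimuth: float,
    constants: OpticalConstants,
    method: str,
) -> np.ndarray:
    """CRP at the unsigned offsets along the hemi-meridian at ``azimuth``."""
    s = grid.samples[_nearest_meridian(grid, azimuth)]
    z = interpolate_hemimeridian(s.radial_mm, s.sag_mm, PROFILE_OFFSETS, method)
    ra = interpolate_hemimeridian(
        s.radial_mm, s.axial_radius_mm, PROFILE_OFFSETS, method
    )
    out = np.full(PROFILE_OFFSETS.shape, np.nan)
    ok = np.isfinite(z) & np.isfinite(ra) & (ra > PROFILE_OFFSETS)
    if np.any(ok):
        out[ok] = crp_at(PROFILE_OFFSETS[ok], z[ok], ra[ok], constants)
    return out


def crp_profile(
    grid: TopographyGrid,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
    *,
    method: Literal["pchip", "linear"] = "pchip",
    nasal_angle: float | None = None,
) -> tuple[MeridianProfile, MeridianProfile]:
    """Horizontal and vertical CRP profiles of one map.

    Sag and axial radius are interpolated at the fixed 0.5 mm offsets
    along the four principal hemi-meridians, CRP is evaluated at each
    offset, and the hemi-meridians are assembled into signed profiles:
    positive positions are nasal (horizontal) and superior (vertical).
    The nasal azimuth defaults to 0 deg for right eyes and 180 deg for
    left eyes (topographer convention, counterclockwise positive); pass
    ``nasal_angle`` to override.
    """
    if nasal_angle is None:
        nasal_angle = 0.0 if grid.eye == "right" else 180.0
    temporal_angle = (nasal_angle + 180.0) % 360.0
    nasal = _hemi_crp(grid, nasal_angle, constants, method)
    temporal = _hemi_crp(grid, temporal_angle, constants, method)
    superior = _hemi_crp(grid, 90.0, constants, method)
    inferior = _hemi_crp(grid, 270.0, constants, method)
    horizontal = MeridianProfile(
        "horizontal", PROFILE_POSITIONS.copy(),
        np.concatenate([temporal[::-1], nasal]), label=grid.map_id,
    )
    vertical = MeridianProfile(
        "vertical", PROFILE_POSITIONS.copy(),
        np.concatenate([inferior[::-1], superior]), label=grid.map_id,
    )
    return horizontal, vertical


def average_maps(profiles: Sequence[MeridianProfile]) -> MeridianProfile:
    """Per-position arithmetic mean over replicate maps of one visit.

    A position missing in more than half of the maps is reported
    missing (with a logged warning); otherwise the mean is taken over
    the maps where it is present.
    """
    if len(profiles) == 0:
        raise ValueError("average_maps requires at least one profile")
    meridian = profiles[0].meridian
    if any(p.meridian != meridian for p in profiles):
        raise ValueError("profiles mix meridians")
    stack = np.vstack([p.crp for p in profiles])
    present = np.isfinite(stack)
    counts = present.sum(axis=0)
    n = len(profiles)
    keep = counts > n / 2.0  # missing in > half the maps -> missing
    dropped = np.isfinite(stack).any(axis=0) & ~keep
    if np.any(dropped):
        log.warning(
            "average_maps(%s): dropping positions %s present in <= half of %d maps",
            meridian, PROFILE_POSITIONS[dropped].tolist(), n,
        )
    mean = np.full(stack.shape[1], np.nan)
    with np.errstate(invalid="ignore"):
        sums = np.where(present, stack, 0.0).sum(axis=0)
        mean[keep] = sums[keep] / counts[keep]
    return MeridianProfile(
        meridian, PROFILE_POSITIONS.copy(), mean,
        n_maps=np.where(keep, counts, 0),
    )
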