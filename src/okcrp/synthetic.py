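"""Synthetic corneas with known ground truth.

Baseline corneas are conic surfaces of revolution (apical radius ``r0``,
asphericity ``Q``; Q < 0 prolate).  Orthokeratology remodelling is
simulated by *specifying the corneal refractive power change* the
treatment should produce -- a wide, flat-topped central flattening plus
a Gaussian annulus of paracentral steepening, optionally decentred --
and solving for the post-treatment sagittal height that realises it.
Because the Klein-Mandell power at radial distance ``x`` depends only on
the sag ``z`` and the meridional slope ``dz/dx`` (through the axial
radius ``r_a = x sqrt(1 + z'^2) / z'``), the target power profile
defines a first-order ODE for ``z`` which is integrated outward from the
apex.  The perturbation field rides with the treatment centre, so for a
decentred zone the sampled grid shows the emergent nasal-temporal
asymmetry of an axis-referenced power map rather than an imposed one.

Grids emulate the raw videokeratoscope export: up to 300 hemi-meridians
(1.2 deg apart) of 32 radial samples spanning 0.25-4.5 mm.  Measurement
noise is a single physical source -- Gaussian perturbation of sagittal
height, micrometre scale -- and the axial radius is re-derived from the
noisy heights via Savitzky-Golay differentiation, keeping ``(x, z,
r_a)`` mutually consistent the way the power formula assumes.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterator, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.signal import savgol_filter

from .crp import DEFAULT_CONSTANTS, OpticalConstants, crp_at
from .topo_io import MeridianSamples, TopographyGrid

__all__ = [
    "ConicSurface",
    "TreatmentProfile",
    "TreatedSurface",
    "CohortSpec",
    "SubjectData",
    "CalibrationError",
    "conic_sag",
    "conic_slope",
    "conic_axial_radius",
    "power_change_target",
    "apply_treatment",
    "sample_grid",
    "generate_cohort",
]

log = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    """Surface inversion failed to realise the programmed power change."""


@dataclass(frozen=True)
class ConicSurface:
    """Conic surface of revolution: apical radius r0 (mm), asphericity Q."""

    r0: float
    q: float = 0.0
    diameter: float = 9.0  # modelled corneal chord, mm

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("apical radius must be positive")
        x_max = self.diameter / 2.0
        if (1 + self.q) * x_max**2 >= self.r0**2:
            raise ValueError("sag undefined over the modelled chord")


def _domain_check(x: np.ndarray, surface: ConicSurface) -> None:
    if np.any((1 + surface.q) * x**2 >= surface.r0**2):
        raise ValueError("radial offset outside the conic sag domain")


def conic_sag(x, surface: ConicSurface):
    """Sag z(x) = x^2 / (r0 (1 + sqrt(1 - (1+Q) x^2 / r0^2))), mm."""
    x = np.asarray(x, dtype=float)
    _domain_check(x, surface)
    r0, q = surface.r0, surface.q
    return x**2 / (r0 * (1 + np.sqrt(1 - (1 + q) * x**2 / r0**2)))


def conic_slope(x, surface: ConicSurface):
    """Meridional slope dz/dx = x / sqrt(r0^2 - (1+Q) x^2)."""
    x = np.asarray(x, dtype=float)
    _domain_check(x, surface)
    return x / np.sqrt(surface.r0**2 - (1 + surface.q) * x**2)


def conic_axial_radius(x, surface: ConicSurface):
    """Axial radius r_a(x) = sqrt(r0^2 - Q x^2), mm.

    Distance along the surface normal from (x, z) to the instrument
    axis; equal to ``x sqrt(1 + z'^2) / z'`` for the conic.
    """
    x = np.asarray(x, dtype=float)
    val = surface.r0**2 - surface.q * x**2
    if np.any(val <= 0):
        raise ValueError("axial radius undefined (r0^2 - Q x^2 <= 0)")
    return np.sqrt(val)


@dataclass(frozen=True)
class TreatmentProfile:
    """Programmed orthokeratology power-change pattern.

    ``delta_center`` is the CRP change (D, negative = flattening)
    programmed at the corneal-centre measurement locations (0.5 mm);
    ``annulus_amp`` the peak paracentral CRP increase (D) at radial
    location ``annulus_radius`` (mm) with Gaussian width
    ``annulus_sigma`` (mm); ``center_sigma`` (mm) is the width of the
    flat-topped central flattening.  ``decenter_x`` > 0 shifts the
    treatment zone toward the nasal cornea, ``decenter_y`` > 0 toward
    the superior cornea (mm).
    """

    delta_center: float = 0.0
    annulus_amp: float = 0.0
    annulus_radius: float = 3.0
    annulus_sigma: float = 0.6
    center_sigma: float = 1.5
    decenter_x: float = 0.0
    decenter_y: float = 0.0

    def __post_init__(self) -> None:
        if self.annulus_sigma <= 0 or self.center_sigma <= 0:
            raise ValueError("treatment widths must be positive")
        if not (0 < self.annulus_radius < 4.5):
            raise ValueError("annulus radius must lie inside the modelled cornea")

    @property
    def is_null(self) -> bool:
        return self.delta_center == 0.0 and self.annulus_amp == 0.0


def power_change_target(d, profile: TreatmentProfile):
    """Programmed CRP change (D) at distance ``d`` from the zone centre.

    Super-Gaussian (order 4) central flattening plus a Gaussian annulus.
    The central amplitude is scaled so the field equals ``delta_center``
    exactly at d = 0.5 mm -- the corneal-centre measurement location --
    after accounting for the annulus tail there; the annulus peak is
    ``annulus_amp`` above zero at ``annulus_radius``.
    """
    d = np.asarray(d, dtype=float)
    p = profile
    ann = p.annulus_amp * np.exp(-((d - p.annulus_radius) ** 2) / (2 * p.annulus_sigma**2))
    ann_at_center = p.annulus_amp * math.exp(
        -((0.5 - p.annulus_radius) ** 2) / (2 * p.annulus_sigma**2)
    )
    a_c = (p.delta_center - ann_at_center) / math.exp(-((0.5 / p.center_sigma) ** 4))
    return a_c * np.exp(-((d / p.center_sigma) ** 4)) + ann


def _solve_incidence(delta: np.ndarray, n_prime: float) -> np.ndarray:
    """Solve u - asin(sin u / n') = delta for the incident angle u."""
    delta = np.asarray(delta, dtype=float)
    u = delta / (1 - 1 / n_prime)  # small-angle initialisation
    for _ in range(60):
        su = np.sin(u)
        f = u - np.arcsin(su / n_prime) - delta
        fp = 1 - np.cos(u) / (n_prime * np.sqrt(1 - (su / n_prime) ** 2))
        step = f / fp
        u = u - step
        if np.max(np.abs(step)) < 1e-15:
            break
    return u


@dataclass(frozen=True)
class TreatedSurface:
    """Post-treatment surface: baseline conic plus a radial sag field.

    The sag perturbation ``delta(d)`` (a PCHIP interpolant of the ODE
    solution) is centred on the treatment zone; sag is re-referenced so
    it vanishes on the instrument axis, as a videokeratoscope reports
    it.  Slope and axial radius come from the exact derivative of the
    interpolant, so sag and axial radius stay mutually consistent.
    """

    base: ConicSurface
    profile: TreatmentProfile
    _delta: PchipInterpolator = field(repr=False)
    _d_max: float = field(repr=False, default=6.0)

    def _field(self, x, phi_deg):
        x = np.asarray(x, dtype=float)
        phi = np.deg2rad(np.asarray(phi_deg, dtype=float))
        p = self.profile
        proj = p.decenter_x * np.cos(phi) + p.decenter_y * np.sin(phi)
        off2 = p.decenter_x**2 + p.decenter_y**2
        d = np.sqrt(np.maximum(x**2 - 2 * x * proj + off2, 0.0))
        return d, proj

    def sag(self, x, phi_deg=0.0):
        x = np.asarray(x, dtype=float)
        d, _ = self._field(x, phi_deg)
        piston = float(self._delta(min(math.hypot(
            self.profile.decenter_x, self.profile.decenter_y), self._d_max)))
        return conic_sag(x, self.base) + self._delta(np.minimum(d, self._d_max)) - piston

    def slope(self, x, phi_deg=0.0):
        x = np.asarray(x, dtype=float)
        d, proj = self._field(x, phi_deg)
        ddx = np.where(d > 1e-9, (x - proj) / np.maximum(d, 1e-9), 0.0)
        dd = np.where(d < self._d_max, self._delta.derivative()(np.minimum(d, self._d_max)), 0.0)
        return conic_slope(x, self.base) + dd * ddx

    def axial_radius(self, x, phi_deg=0.0):
        x = np.asarray(x, dtype=float)
        p = self.slope(x, phi_deg)
        with np.errstate(divide="ignore"):
            return np.where(x == 0, self.base.r0, x * np.sqrt(1 + p**2) / np.maximum(p, 1e-12))


def apply_treatment(
    surface: ConicSurface,
    profile: TreatmentProfile,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
    *,
    d_max: float = 6.0,
    n_knots: int = 1201,
    tol: float = 0.05,
) -> ConicSurface | TreatedSurface:
    """Solve for the post-treatment surface realising ``profile``.

    The target power profile ``P_post(d) = P_pre(d) + dP(d)`` (with
    ``dP`` from :func:`power_change_target`) is inverted for sag: at
    each radius the Klein-Mandell relation fixes the ray deviation
    ``theta_i - theta_t`` and hence, via Snell's law, the meridional
    slope, giving ``dz/dx = F(x, z)`` which is integrated from the apex.
    The achieved power change is verified at the centre location and at
    the annulus peak to within ``tol`` (D); failure raises
    :class:`CalibrationError` with diagnostics.

    A null profile returns ``surface`` unchanged, so null-treatment
    grids are bit-identical to baseline grids.
    """
    if profile.is_null:
        return surface
    n_prime = constants.n_prime

    def target_power(x: float) -> float:
        if x == 0:
            base = (n_prime - 1.0) / (surface.r0 / 1000.0)
        else:
            base = crp_at(x, conic_sag(x, surface),
                          conic_axial_radius(x, surface), constants)
        return base + float(power_change_target(x, profile))

    def rhs(x: float, z: np.ndarray) -> list[float]:
        if x == 0:
            return [0.0]
        g_mm = 1000.0 * n_prime / target_power(x) - z[0]
        dev = math.atan2(x, g_mm)
        u = float(_solve_incidence(np.array(dev), n_prime))
        return [math.tan(u)]

    knots = np.linspace(0.0, d_max, n_knots)
    sol = solve_ivp(rhs, (0.0, d_max), [0.0], t_eval=knots,
                    rtol=1e-10, atol=1e-13, method="RK45")
    if not sol.success:
        raise CalibrationError(f"surface inversion failed: {sol.message}")
    delta_sag = sol.y[0] - conic_sag(knots, surface)
    interp = PchipInterpolator(knots, delta_sag)
    treated = TreatedSurface(surface, profile, interp, d_max)

    # verify the realised power change at the calibration points, in the
    # treatment-centred frame (a decentred zone deviates by construction
    # when measured about the instrument axis)
    centred = (treated if profile.decenter_x == profile.decenter_y == 0.0
               else TreatedSurface(
                   surface, replace(profile, decenter_x=0.0, decenter_y=0.0),
                   interp, d_max))
    for x_chk, want in (
        (0.5, profile.delta_center),
        (profile.annulus_radius, float(power_change_target(profile.annulus_radius, profile))),
    ):
        got = crp_at(x_chk, centred.sag(x_chk), centred.axial_radius(x_chk),
                     constants) - crp_at(
            x_chk, conic_sag(x_chk, surface), conic_axial_radius(x_chk, surface),
            constants)
        if abs(got - want) > tol:
            raise CalibrationError(
                f"achieved power change {got:+.4f} D at {x_chk:g} mm, "
                f"programmed {want:+.4f} D (|diff| > {tol:g} D)"
            )
    return treated


def _surface_sag(surface, x, phi_deg):
    if isinstance(surface, TreatedSurface):
        return surface.sag(x, phi_deg)
    return np.broadcast_to(conic_sag(x, surface), np.broadcast(
        np.asarray(x, float), np.asarray(phi_deg, float)).shape).copy()


def _surface_slope(surface, x, phi_deg):
    if isinstance(surface, TreatedSurface):
        return surface.slope(x, phi_deg)
    return np.broadcast_to(conic_slope(x, surface), np.broadcast(
        np.asarray(x, float), np.asarray(phi_deg, float)).shape).copy()


def sample_grid(
    surface: ConicSurface | TreatedSurface,
    *,
    n_meridians: int = 300,
    samples_per_meridian: int = 32,
    noise_sd_um: float = 0.0,
    seed: int | np.random.Generator | None = None,
    map_id: str = "map",
    eye: str = "right",
    visit: str = "baseline",
    meta: dict[str, str] | None = None,
    r_min: float = 0.25,
    r_max: float = 4.5,
) -> TopographyGrid:
    """Sample a surface onto a videokeratoscope-style polar grid.

    Meridians are equally spaced over 360 deg; radial samples span
    ``r_min``-``r_max`` mm (bracketing the 0.5-4.0 mm analysis range so
    downstream interpolation never extrapolates).  With noise off the
    sag and slope are analytic and the axial radius exact.  With noise
    on, independent N(0, ``noise_sd_um``) perturbations (micrometres)
    are added to the sag of every sample, monotonicity along each ray is
    restored by a running maximum, and the slope -- hence the axial
    radius -- is re-derived from the noisy heights by Savitzky-Golay
    differentiation, as a topographer's smoothed processing would.

    Identical ``seed`` gives an identical grid.
    """
    if n_meridians < 1 or samples_per_meridian < 1:
        raise ValueError("counts must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(0 if seed is None else seed))
    radii = np.linspace(r_min, r_max, samples_per_meridian)
    angles = np.arange(n_meridians) * (360.0 / n_meridians)
    xg, ag = np.meshgrid(radii, angles)  # (n_mer, n_samp)

    z = _surface_sag(surface, xg, ag)
    if noise_sd_um > 0:
        z = z + rng.normal(0.0, noise_sd_um * 1e-3, z.shape)
        z = np.maximum.accumulate(np.maximum(z, 0.0), axis=1)
        window = min(9, samples_per_meridian if samples_per_meridian % 2 else samples_per_meridian - 1)
        if window >= 3:
            order = min(3, window - 1)
            h = radii[1] - radii[0] if samples_per_meridian > 1 else 1.0
            p = savgol_filter(z, window, order, deriv=1, delta=h, axis=1)
        else:
            p = _surface_slope(surface, xg, ag)
    else:
        p = _surface_slope(surface, xg, ag)
    p = np.maximum(p, 1e-6)
    ra = xg * np.sqrt(1 + p**2) / p

    samples = [
        MeridianSamples(radial_mm=radii.copy(), sag_mm=z[i], axial_radius_mm=ra[i],
                        slope=p[i])
        for i in range(n_meridians)
    ]
    return TopographyGrid(
        map_id=map_id, eye=eye, visit=visit, meridian_angles=angles,
        samples=samples, meta=dict(meta or {}),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Distributions defining a synthetic pre/post orthokeratology cohort.

    Baseline apical radius defaults to 7.80 +/- 0.22 mm; asphericity to
    Q = -0.25 +/- 0.10 (a typical prolate adult cornea -- an assumption,
    baseline asphericity is not part of the emulated study summary).
    Treatment defaults programme ~2 D of central flattening and a
    ~2.5 D paracentral annulus at 3 mm, i.e. a programmed maximum
    relative paracentral change near 4.5 D and central-paracentral
    ratio near 2.25.  Four replicate maps per visit with 0.3 um sag
    noise emulate clinical repeat captures.

    If ``cpc_ratio_target`` is set, the annulus amplitude is derived per
    subject as ``(ratio - 1) * |delta_center|`` with the ratio drawn
    from N(target, jitter), so the per-subject central-paracentral ratio
    is programmed directly (used for parameter-recovery studies).
    """

    n_subjects: int = 19
    r0_mean: float = 7.80
    r0_sd: float = 0.22
    q_mean: float = -0.25
    q_sd: float = 0.10
    delta_center_mean: float = -2.0
    delta_center_sd: float = 0.8
    annulus_amp_mean: float = 2.5
    annulus_amp_sd: float = 0.7
    annulus_radius_mean: float = 3.0
    annulus_radius_sd: float = 0.25
    annulus_sigma_mean: float = 0.6
    annulus_sigma_sd: float = 0.05
    center_sigma_mean: float = 1.5
    center_sigma_sd: float = 0.10
    decenter_x_mean: float = 0.0
    decenter_x_sd: float = 0.0
    decenter_y_mean: float = 0.0
    decenter_y_sd: float = 0.0
    cpc_ratio_target: float | None = None
    cpc_ratio_jitter: float = 0.0
    maps_per_visit: int = 4
    n_meridians: int = 300
    samples_per_meridian: int = 32
    noise_sd_um: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.maps_per_visit < 1:
            raise ValueError("maps_per_visit must be >= 1")
        for f in fields(self):
            if f.name.endswith("_sd") and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")


@dataclass
class SubjectData:
    """One synthetic subject: surfaces, ground truth and captured maps."""

    subject: str
    surface: ConicSurface
    treatment: TreatmentProfile
    baseline: list[TopographyGrid]
    post: list[TopographyGrid]


def _draw(rng: np.random.Generator, mean: float, sd: float,
          lo: float = -np.inf, hi: float = np.inf) -> float:
    return float(np.clip(rng.normal(mean, sd) if sd > 0 else mean, lo, hi))


def generate_cohort(spec: CohortSpec) -> list[SubjectData]:
    """Generate a fully reproducible pre/post cohort with ground truth.

    Per subject: a baseline conic, a treatment profile drawn from the
    spec's distributions, ``maps_per_visit`` baseline maps of the conic
    and the same number of post maps of the treated surface, all with
    independent measurement noise.  Everything derives from
    ``spec.seed`` alone.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[SubjectData] = []
    for i in range(spec.n_subjects):
        sid = f"S{i + 1:02d}"
        surface = ConicSurface(
            r0=_draw(rng, spec.r0_mean, spec.r0_sd, 6.5, 9.5),
            q=_draw(rng, spec.q_mean, spec.q_sd, -0.95, 0.40),
        )
        dc = _draw(rng, spec.delta_center_mean, spec.delta_center_sd)
        if spec.cpc_ratio_target is not None:
            ratio = _draw(rng, spec.cpc_ratio_target, spec.cpc_ratio_jitter)
            amp = max((ratio - 1.0) * abs(dc), 0.0)
        else:
            amp = _draw(rng, spec.annulus_amp_mean, spec.annulus_amp_sd, 0.0)
        treatment = TreatmentProfile(
            delta_center=dc,
            annulus_amp=amp,
            annulus_radius=_draw(rng, spec.annulus_radius_mean,
                                 spec.annulus_radius_sd, 2.0, 4.0),
            annulus_sigma=_draw(rng, spec.annulus_sigma_mean,
                                spec.annulus_sigma_sd, 0.2, 1.5),
            center_sigma=_draw(rng, spec.center_sigma_mean,
                               spec.center_sigma_sd, 0.8, 2.5),
            decenter_x=_draw(rng, spec.decenter_x_mean, spec.decenter_x_sd),
            decenter_y=_draw(rng, spec.decenter_y_mean, spec.decenter_y_sd),
        )
        treated = apply_treatment(surface, treatment)
        common = dict(
            n_meridians=spec.n_meridians,
            samples_per_meridian=spec.samples_per_meridian,
            noise_sd_um=spec.noise_sd_um,
            meta={"subject": sid},
        )
        baseline = [
            sample_grid(surface, seed=rng, map_id=f"{sid}_baseline_{k}",
                        visit="baseline", **common)
            for k in range(spec.maps_per_visit)
        ]
        post = [
            sample_grid(treated, seed=rng, map_id=f"{sid}_post_{k}",
                        visit="post", **common)
            for k in range(spec.maps_per_visit)
        ]
        out.append(SubjectData(sid, surface, treatment, baseline, post))
    return out
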