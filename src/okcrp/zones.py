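"""Zonal change analysis and the central-paracentral (CPC) power ratio.

The 16 locations of a meridian profile are split into the corneal
centre (the 1 mm chord: the two +/-0.5 mm locations), the central
region (4 mm chord: 8 locations) and the two paracentral regions
(5-8 mm chord: 4 locations per side).  Per subject and meridian the
centre change is the mean power change at the two centre locations; the
maximum paracentral change *relative to the centre change* is taken per
side (a maximum, not an average, so a decentred or large treatment zone
is not masked); and the CPC power ratio is that relative maximum
divided by the magnitude of the centre change.  Cohort summaries use
the mean of the per-subject ratios, not the ratio of means.

Cohort statistics follow a normality-gated scheme: per location (or per
derived summary) a Shapiro-Wilk test at alpha = 0.05 routes to a paired
t test on the changes when normal, a Wilcoxon signed-rank test
otherwise; per-location p values are Bonferroni-corrected within the 16
locations of the meridian.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .crp import PROFILE_POSITIONS, MeridianProfile

__all__ = [
    "ZoneDefinition",
    "ChangeProfile",
    "RegionCPC",
    "SubjectCPC",
    "MissingDataError",
    "change_profile",
    "center_change",
    "max_relative_paracentral",
    "cpc_ratio",
    "cohort_cpc",
    "location_tests",
    "asymmetry_test",
    "center_paracentral_correlation",
    "region_name",
]

log = logging.getLogger(__name__)

NORMALITY_ALPHA = 0.05


class MissingDataError(ValueError):
    """Required locations are missing from a change profile."""


@dataclass(frozen=True)
class ZoneDefinition:
    """Radial zone boundaries (mm, half-chord) on the 0.5 mm grid."""

    center_max: float = 0.5       # corneal centre: 1 mm chord
    central_max: float = 2.0      # central region: 4 mm chord
    paracentral_min: float = 2.5  # paracentral region: 5-8 mm chord
    paracentral_max: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.center_max <= self.central_max
                < self.paracentral_min <= self.paracentral_max):
            raise ValueError("zone boundaries must be ordered")
        for v in (self.center_max, self.central_max,
                  self.paracentral_min, self.paracentral_max):
            if abs(v / 0.5 - round(v / 0.5)) > 1e-9:
                raise ValueError("zone boundaries must be multiples of 0.5 mm")


@dataclass
class ChangeProfile:
    """Per-location CRP change (post - baseline) for one subject/meridian."""

    subject: str
    meridian: Literal["horizontal", "vertical"]
    positions: np.ndarray
    delta_crp: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.delta_crp = np.asarray(self.delta_crp, dtype=float)
        if not np.array_equal(self.positions, PROFILE_POSITIONS):
            raise ValueError("positions must be the fixed +/-0.5..4.0 mm grid")


@dataclass
class RegionCPC:
    """CPC summary of one paracentral region for one subject."""

    region: str
    max_relative_change: float
    argmax_position: float
    cpc_ratio: float | None


@dataclass
class SubjectCPC:
    """Per-subject centre change and paracentral CPC summaries."""

    subject: str
    meridian: str
    center_change: float
    regions: dict[str, RegionCPC] = field(default_factory=dict)


def region_name(meridian: str, side: Literal["positive", "negative"]) -> str:
    """Anatomical name of a paracentral region (right-eye convention)."""
    if meridian == "horizontal":
        return "nasal" if side == "positive" else "temporal"
    return "superior" if side == "positive" else "inferior"


def change_profile(pre: MeridianProfile, post: MeridianProfile,
                   subject: str = "") -> ChangeProfile:
    """Per-location power change, post minus baseline.

    Missing on either visit propagates to missing in the change.
    """
    if pre.meridian != post.meridian:
        raise ValueError("meridian mismatch between visits")
    delta = post.crp - pre.crp  # NaN propagates
    return ChangeProfile(subject, pre.meridian, PROFILE_POSITIONS.copy(), delta)


def center_change(delta: ChangeProfile,
                  zones: ZoneDefinition = ZoneDefinition()) -> float:
    """Mean change at the two corneal-centre locations (+/-0.5 mm).

    The centre is mandatory: either location missing raises
    :class:`MissingDataError`.
    """
    vals = []
    for pos in (-zones.center_max, zones.center_max):
        idx = np.flatnonzero(np.isclose(delta.positions, pos))
        v = delta.delta_crp[idx[0]]
        if not np.isfinite(v):
            raise MissingDataError(
                f"centre location {pos:+.1f} mm missing for {delta.subject or 'subject'}"
            )
        vals.append(float(v))
    return float(np.mean(vals))


def max_relative_paracentral(
    delta: ChangeProfile,
    zones: ZoneDefinition = ZoneDefinition(),
    side: Literal["positive", "negative"] = "positive",
) -> tuple[float, float]:
    """Maximum paracentral change relative to the centre change, one side.

    Returns ``(max_relative_change, argmax_position_mm)`` where the
    relative change at a location is ``delta(x) - center_change``.  The
    maximum is signed (a uniformly flattened paracentral zone yields a
    negative maximum).  Ties break toward the smaller |x|.
    """
    center = center_change(delta, zones)
    sign = 1.0 if side == "positive" else -1.0
    absx = np.abs(delta.positions)
    mask = (
        (np.sign(delta.positions) == sign)
        & (absx >= zones.paracentral_min - 1e-9)
        & (absx <= zones.paracentral_max + 1e-9)
        & np.isfinite(delta.delta_crp)
    )
    if not np.any(mask):
        raise MissingDataError(
            f"no paracentral coverage on the {side} side for "
            f"{delta.subject or 'subject'}"
        )
    order = np.argsort(absx[mask], kind="stable")
    rel = (delta.delta_crp[mask] - center)[order]
    pos = delta.positions[mask][order]
    best = 0
    for i in range(1, rel.size):
        if rel[i] > rel[best]:  # strict: ties stay at smaller |x|
            best = i
    return float(rel[best]), float(abs(pos[best]))


def cpc_ratio(
    delta: ChangeProfile,
    zones: ZoneDefinition = ZoneDefinition(),
    min_center: float = 0.25,
) -> SubjectCPC:
    """Per-subject CPC power ratios for both paracentral regions.

    ``cpc_ratio = max_relative_change / |center_change|`` per region.
    Subjects whose centre change magnitude falls below ``min_center``
    (D) are non-responders: the ratio is numerically unstable there and
    is reported missing, with a warning.
    """
    center = center_change(delta, zones)
    out = SubjectCPC(delta.subject, delta.meridian, center)
    responder = abs(center) >= min_center
    if not responder:
        warnings.warn(
            f"{delta.subject or 'subject'} ({delta.meridian}): centre change "
            f"{center:+.3f} D below {min_center:g} D threshold; CPC ratio "
            "reported missing (non-responder)",
            stacklevel=2,
        )
    for side in ("positive", "negative"):
        name = region_name(delta.meridian, side)
        max_rel, argmax = max_relative_paracentral(delta, zones, side)
        ratio = max_rel / abs(center) if responder else None
        out.regions[name] = RegionCPC(name, max_rel, argmax, ratio)
    return out


def cohort_cpc(subjects: Sequence[SubjectCPC]) -> pd.DataFrame:
    """Cohort summary of CPC ratios: mean of the per-subject ratios.

    One row per (meridian, region) with n, mean, sd, min and max over
    the subjects with a valid (responder) ratio.
    """
    rows = []
    keys = []
    for s in subjects:
        for name, reg in s.regions.items():
            if reg.cpc_ratio is not None:
                rows.append((s.meridian, name, reg.cpc_ratio))
    if not rows:
        raise ValueError("no valid CPC ratios in cohort")
    df = pd.DataFrame(rows, columns=["meridian", "region", "ratio"])
    agg = (
        df.groupby(["meridian", "region"], sort=True)["ratio"]
        .agg(n="count", mean="mean", sd="std", min="min", max="max")
        .reset_index()
    )
    return agg


def _gated_test(values: np.ndarray) -> tuple[str, float, float]:
    """Normality-gated one-sample test against zero on paired changes.

    Returns (test_name, statistic, p).  Degenerate zero-variance input
    short-circuits: no change -> p = 1, uniform nonzero change -> p = 0.
    """
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        return ("degenerate", 0.0, 1.0 if values[0] == 0 else 0.0)
    sw_p = stats.shapiro(values).pvalue
    if sw_p >= NORMALITY_ALPHA:
        res = stats.ttest_1samp(values, 0.0)
        return ("paired-t", float(res.statistic), float(res.pvalue))
    res = stats.wilcoxon(values)
    return ("wilcoxon", float(res.statistic), float(res.pvalue))


def location_tests(
    profiles: Sequence[ChangeProfile],
    alpha: float = 0.05,
    family: int | None = None,
) -> pd.DataFrame:
    """Per-location tests for significant CRP change across the cohort.

    For each of the 16 meridian locations, the per-subject changes are
    tested against zero with the normality-gated paired scheme;
    Bonferroni correction uses the meridian's 16 locations as the
    family (``family`` overrides).  Locations with fewer than 3
    subjects are reported untested.
    """
    if not profiles:
        raise ValueError("no change profiles supplied")
    meridian = profiles[0].meridian
    if any(p.meridian != meridian for p in profiles):
        raise ValueError("profiles mix meridians")
    stack = np.vstack([p.delta_crp for p in profiles])
    m = family if family is not None else PROFILE_POSITIONS.size
    rows = []
    for j, pos in enumerate(PROFILE_POSITIONS):
        col = stack[:, j]
        col = col[np.isfinite(col)]
        n = col.size
        if n < 3:
            rows.append(dict(meridian=meridian, position_mm=pos, n=n,
                             mean=np.nan, sd=np.nan, test="insufficient-n",
                             statistic=np.nan, p_raw=np.nan, p_adj=np.nan,
                             significant=False))
            log.info("location %+0.1f mm skipped: only %d subjects", pos, n)
            continue
        test, statistic, p_raw = _gated_test(col)
        p_adj = min(1.0, p_raw * m)
        rows.append(dict(meridian=meridian, position_mm=pos, n=n,
                         mean=float(col.mean()), sd=float(col.std(ddof=1)),
                         test=test, statistic=statistic, p_raw=p_raw,
                         p_adj=p_adj, significant=bool(p_adj < alpha)))
    return pd.DataFrame(rows)


def asymmetry_test(
    profiles: Sequence[ChangeProfile],
    zones: ZoneDefinition = ZoneDefinition(),
) -> dict:
    """Test for asymmetry between the two paracentral regions.

    The per-subject statistic is the difference between the positive-
    and negative-side maximum relative paracentral changes; the
    normality-gated paired scheme tests it against zero.  Requires at
    least 3 subjects with both sides available.
    """
    if not profiles:
        raise ValueError("no change profiles supplied")
    meridian = profiles[0].meridian
    diffs = []
    for p in profiles:
        try:
            pos_max, _ = max_relative_paracentral(p, zones, "positive")
            neg_max, _ = max_relative_paracentral(p, zones, "negative")
        except MissingDataError:
            log.info("asymmetry: skipping %s (incomplete coverage)", p.subject)
            continue
        diffs.append(pos_max - neg_max)
    if len(diffs) < 3:
        raise ValueError("asymmetry test requires >= 3 subjects with both sides")
    diffs = np.asarray(diffs)
    test, statistic, p = _gated_test(diffs)
    return dict(
        meridian=meridian, n=len(diffs), mean_difference=float(diffs.mean()),
        test=test, statistic=statistic, p_value=p,
        positive_region=region_name(meridian, "positive"),
        negative_region=region_name(meridian, "negative"),
    )


def center_paracentral_correlation(subjects: Sequence[SubjectCPC]) -> pd.DataFrame:
    """Pearson correlation of centre change vs relative paracentral maximum.

    Per (meridian, region) across subjects; deeper central flattening
    accompanied by stronger relative steepening shows as negative r.
    Requires >= 3 pairs and non-zero variance on both variables.
    """
    buckets: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for s in subjects:
        for name, reg in s.regions.items():
            buckets.setdefault((s.meridian, name), []).append(
                (s.center_change, reg.max_relative_change)
            )
    rows = []
    for (meridian, name), pairs in sorted(buckets.items()):
        if len(pairs) < 3:
            raise ValueError(f"correlation for {meridian}/{name} needs >= 3 pairs")
        center = np.array([p[0] for p in pairs])
        rel = np.array([p[1] for p in pairs])
        if np.ptp(center) == 0 or np.ptp(rel) == 0:
            raise ValueError(
                f"zero variance in {meridian}/{name}: correlation undefined"
            )
        r, p = stats.pearsonr(center, rel)
        rows.append(dict(meridian=meridian, region=name, n=len(pairs),
                         pearson_r=float(r), p_value=float(p)))
    return pd.DataFrame(rows)
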