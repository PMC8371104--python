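"""End-to-end orchestration: grids -> profiles -> changes -> statistics.

Thin glue shared by the command-line interface, the test-suite and the
reproduction script; all science lives in :mod:`okcrp.crp`,
:mod:`okcrp.zones` and :mod:`okcrp.synthetic`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .crp import (DEFAULT_CONSTANTS, PROFILE_POSITIONS, MeridianProfile,
                  OpticalConstants, average_maps, crp_profile)
from .synthetic import SubjectData
from .topo_io import TopographyGrid
from .zones import (ChangeProfile, MissingDataError, SubjectCPC, ZoneDefinition,
                    asymmetry_test, center_paracentral_correlation, change_profile,
                    cohort_cpc, cpc_ratio, location_tests)

__all__ = [
    "MERIDIANS",
    "CohortResults",
    "visit_profiles",
    "subject_changes",
    "analyze_changes",
    "profiles_table",
    "changes_table",
    "subject_cpc_table",
]

log = logging.getLogger(__name__)

MERIDIANS = ("horizontal", "vertical")


def visit_profiles(
    grids: Sequence[TopographyGrid],
    constants: OpticalConstants = DEFAULT_CONSTANTS,
    method: str = "pchip",
) -> dict[str, MeridianProfile]:
    """Average the CRP profiles of one visit's replicate maps."""
    horiz, vert = [], []
    for g in grids:
        h, v = crp_profile(g, constants, method=method)
        horiz.append(h)
        vert.append(v)
    return {"horizontal": average_maps(horiz), "vertical": average_maps(vert)}


def subject_changes(
    subject: str,
    baseline: Sequence[TopographyGrid],
    post: Sequence[TopographyGrid],
    constants: OpticalConstants = DEFAULT_CONSTANTS,
    method: str = "pchip",
) -> dict[str, ChangeProfile]:
    """Per-meridian change profiles (post - baseline) for one subject."""
    pre = visit_profiles(baseline, constants, method)
    pst = visit_profiles(post, constants, method)
    return {
        m: change_profile(pre[m], pst[m], subject=subject) for m in MERIDIANS
    }


@dataclass
class CohortResults:
    """Bundle of every cohort-level output table."""

    changes: dict[str, list[ChangeProfile]]
    subject_cpc: list[SubjectCPC]
    cpc_summary: pd.DataFrame
    location_tests: dict[str, pd.DataFrame]
    asymmetry: dict[str, dict]
    correlations: pd.DataFrame
    skipped: list[tuple[str, str]] = field(default_factory=list)


def analyze_changes(
    changes: Mapping[str, Sequence[ChangeProfile]],
    zones: ZoneDefinition = ZoneDefinition(),
    min_center: float = 0.25,
) -> CohortResults:
    """Full zonal analysis of a cohort's change profiles.

    Subjects whose centre or paracentral coverage is incomplete are
    skipped for the CPC stage (with the reason recorded) but still
    contribute to the per-location tests wherever they have data.
    """
    subject_cpcs: list[SubjectCPC] = []
    skipped: list[tuple[str, str]] = []
    for meridian in MERIDIANS:
        for prof in changes.get(meridian, []):
            try:
                subject_cpcs.append(cpc_ratio(prof, zones, min_center))
            except MissingDataError as exc:
                skipped.append((prof.subject, str(exc)))
                log.warning("CPC skipped: %s", exc)
    loc = {m: location_tests(list(changes[m])) for m in MERIDIANS if changes.get(m)}
    asym: dict[str, dict] = {}
    for m in MERIDIANS:
        if not changes.get(m):
            continue
        try:
            asym[m] = asymmetry_test(list(changes[m]), zones)
        except ValueError as exc:
            log.warning("asymmetry test unavailable for %s: %s", m, exc)
    try:
        summary = cohort_cpc(subject_cpcs)
    except ValueError:
        summary = pd.DataFrame(
            columns=["meridian", "region", "n", "mean", "sd", "min", "max"]
        )
    try:
        corr = center_paracentral_correlation(subject_cpcs)
    except ValueError as exc:
        log.warning("correlation unavailable: %s", exc)
        corr = pd.DataFrame(columns=["meridian", "region", "n", "pearson_r", "p_value"])
    return CohortResults(
        changes={m: list(v) for m, v in changes.items()},
        subject_cpc=subject_cpcs,
        cpc_summary=summary,
        location_tests=loc,
        asymmetry=asym,
        correlations=corr,
        skipped=skipped,
    )


def profiles_table(
    rows: Iterable[tuple[str, str, MeridianProfile]]
) -> pd.DataFrame:
    """Long table of averaged profiles: (subject, visit, profile) rows."""
    recs = []
    for subject, visit, prof in rows:
        nm = prof.n_maps if prof.n_maps is not None else np.full(
            PROFILE_POSITIONS.size, np.nan)
        for pos, val, n in zip(prof.positions, prof.crp, nm):
            recs.append(dict(subject=subject, visit=visit, meridian=prof.meridian,
                             position_mm=pos, crp_D=val, n_maps_used=n))
    return pd.DataFrame(recs)


def changes_table(changes: Mapping[str, Sequence[ChangeProfile]]) -> pd.DataFrame:
    recs = []
    for meridian in MERIDIANS:
        for prof in changes.get(meridian, []):
            for pos, val in zip(prof.positions, prof.delta_crp):
                recs.append(dict(subject=prof.subject, meridian=meridian,
                                 position_mm=pos, delta_crp_D=val))
    return pd.DataFrame(recs)


def subject_cpc_table(subject_cpcs: Sequence[SubjectCPC]) -> pd.DataFrame:
    recs = []
    for s in subject_cpcs:
        for name, reg in s.regions.items():
            recs.append(dict(
                subject=s.subject, meridian=s.meridian,
                center_change_D=s.center_change, region=name,
                max_relative_change_D=reg.max_relative_change,
                argmax_position_mm=reg.argmax_position,
                cpc_ratio=np.nan if reg.cpc_ratio is None else reg.cpc_ratio,
            ))
    return pd.DataFrame(recs)
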