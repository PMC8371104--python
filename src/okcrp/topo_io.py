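"""Read, validate and write polar-grid corneal topography maps.

A map is a polar grid of per-hemi-meridian samples, emulating the raw
export of a Placido videokeratoscope: for each hemi-meridian (up to 300,
uniformly spaced in azimuth) up to 32 radial samples carrying the radial
distance from the videokeratoscopic centre, the sagittal height, the
axial radius of curvature and optionally the tangential radius and the
meridional slope.

File dialect
------------
One long CSV per map.  Metadata is carried in ``#``-prefixed header
lines (``# key: value``); the mandatory keys are ``map_id``, ``eye``
(``right``/``left``) and ``visit`` (``baseline``/``post``), any further
keys are preserved in :attr:`TopographyGrid.meta`.  Data columns::

    meridian_deg, radial_mm, sag_mm, axial_radius_mm,
    tangential_radius_mm, slope

The last two columns are optional (empty cells allowed).  Missing
peripheral coverage is encoded by *absent rows*, never by sentinel
values.  Numbers are serialised with 10 significant digits so a
write/read round trip is value-exact at that precision.

Angle convention: azimuth 0 deg is the nasal hemi-meridian of a right
eye, counterclockwise positive (90 deg superior).  For left eyes the
nasal hemi-meridian is at 180 deg; downstream code resolves this from
the ``eye`` metadata (see :func:`okcrp.crp.crp_profile`).
"""
from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MeridianSamples",
    "TopographyGrid",
    "Violation",
    "TopographyFormatError",
    "TopographyValidationError",
    "read_grid",
    "write_grid",
    "validate_grid",
    "MAX_MERIDIANS",
    "MAX_SAMPLES",
]

MAX_MERIDIANS = 300
MAX_SAMPLES = 32

REQUIRED_COLUMNS = ("meridian_deg", "radial_mm", "sag_mm", "axial_radius_mm")
OPTIONAL_COLUMNS = ("tangential_radius_mm", "slope")


class TopographyFormatError(ValueError):
    """The file does not follow the long-CSV topography dialect."""


class TopographyValidationError(ValueError):
    """A parsed grid violates a structural invariant."""


@dataclass
class MeridianSamples:
    """Radial samples of one hemi-meridian, ordered by radial distance."""

    radial_mm: np.ndarray
    sag_mm: np.ndarray
    axial_radius_mm: np.ndarray
    tangential_radius_mm: np.ndarray | None = None
    slope: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.radial_mm = np.asarray(self.radial_mm, dtype=float)
        self.sag_mm = np.asarray(self.sag_mm, dtype=float)
        self.axial_radius_mm = np.asarray(self.axial_radius_mm, dtype=float)
        for name in ("tangential_radius_mm", "slope"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, np.asarray(val, dtype=float))

    @property
    def n(self) -> int:
        return int(self.radial_mm.size)


@dataclass
class TopographyGrid:
    """One captured topography map: polar grid of hemi-meridian samples."""

    map_id: str
    eye: str
    visit: str
    meridian_angles: np.ndarray
    samples: list[MeridianSamples]
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.meridian_angles = np.asarray(self.meridian_angles, dtype=float)
        if len(self.samples) != self.meridian_angles.size:
            raise TopographyValidationError(
                "samples list length does not match meridian_angles"
            )

    @property
    def n_meridians(self) -> int:
        return int(self.meridian_angles.size)

    @property
    def n_rows(self) -> int:
        """Total number of present samples (rows in the serialized file)."""
        return sum(s.n for s in self.samples)


@dataclass(frozen=True)
class Violation:
    """One invariant violation, locating the offending meridian/sample."""

    rule: str
    meridian_deg: float | None
    sample_index: int | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = ""
        if self.meridian_deg is not None:
            loc = f" [meridian {self.meridian_deg:g} deg"
            if self.sample_index is not None:
                loc += f", sample {self.sample_index}"
            loc += "]"
        return f"{self.rule}{loc}: {self.message}"


def validate_grid(grid: TopographyGrid) -> list[Violation]:
    """Check every structural invariant of a grid.

    Returns an empty list iff the grid is valid; reports, never raises.
    """
    out: list[Violation] = []
    ang = grid.meridian_angles
    n = ang.size
    if n == 0:
        out.append(Violation("empty-grid", None, None, "grid has no meridians"))
        return out
    if n > MAX_MERIDIANS:
        out.append(
            Violation(
                "too-many-meridians", None, None,
                f"{n} meridians exceeds the maximum of {MAX_MERIDIANS}",
            )
        )
    if np.any(ang < 0) or np.any(ang >= 360):
        out.append(
            Violation("angle-range", None, None, "angles must lie in [0, 360)")
        )
    if np.any(np.diff(ang) <= 0):
        out.append(
            Violation("angle-order", None, None, "angles must be strictly ascending")
        )
    elif n > 1:
        spacing = 360.0 / n
        expect = ang[0] + spacing * np.arange(n)
        if np.max(np.abs(ang - expect)) > 1e-9:
            out.append(
                Violation(
                    "non-uniform spacing", None, None,
                    f"angles deviate from uniform {spacing:g} deg spacing",
                )
            )
    if grid.eye not in ("right", "left"):
        out.append(Violation("eye", None, None, f"unknown eye {grid.eye!r}"))
    if grid.visit not in ("baseline", "post"):
        out.append(Violation("visit", None, None, f"unknown visit {grid.visit!r}"))

    for a, s in zip(ang, grid.samples):
        if s.n > MAX_SAMPLES:
            out.append(
                Violation(
                    "too-many-samples", float(a), None,
                    f"{s.n} samples exceeds the maximum of {MAX_SAMPLES}",
                )
            )
        r = s.radial_mm
        if np.any(r < 0):
            out.append(
                Violation("negative radius", float(a), int(np.argmax(r < 0)),
                          "radial_mm must be >= 0")
            )
        if r.size > 1 and np.any(np.diff(r) <= 0):
            idx = int(np.argmax(np.diff(r) <= 0)) + 1
            out.append(
                Violation("non-increasing radius", float(a), idx,
                          "radial_mm must be strictly increasing")
            )
        if np.any(~np.isfinite(r)) or np.any(~np.isfinite(s.sag_mm)) or np.any(
            ~np.isfinite(s.axial_radius_mm)
        ):
            out.append(
                Violation("non-finite", float(a), None,
                          "radial, sag and axial radius must be finite")
            )
            continue
        if np.any(s.axial_radius_mm <= 0):
            idx = int(np.argmax(s.axial_radius_mm <= 0))
            out.append(
                Violation("non-positive axial radius", float(a), idx,
                          "axial_radius_mm must be > 0")
            )
        if np.any(s.sag_mm < 0):
            idx = int(np.argmax(s.sag_mm < 0))
            out.append(
                Violation("negative sag", float(a), idx, "sag_mm must be >= 0")
            )
        if s.n > 1 and np.any(np.diff(s.sag_mm) < 0):
            idx = int(np.argmax(np.diff(s.sag_mm) < 0)) + 1
            out.append(
                Violation("decreasing sag", float(a), idx,
                          "sag_mm must be non-decreasing in radial_mm")
            )
        bad = r > s.axial_radius_mm
        if np.any(bad):
            idx = int(np.argmax(bad))
            out.append(
                Violation(
                    "radial exceeds axial radius", float(a), idx,
                    "radial_mm must not exceed axial_radius_mm "
                    "(incident angle undefined otherwise)",
                )
            )
    return out


def _check(grid: TopographyGrid) -> None:
    violations = validate_grid(grid)
    if violations:
        msgs = "; ".join(str(v) for v in violations[:5])
        more = f" (+{len(violations) - 5} more)" if len(violations) > 5 else ""
        raise TopographyValidationError(f"invalid topography grid: {msgs}{more}")


def read_grid(path: str | Path) -> TopographyGrid:
    """Read and validate one topography map in the long-CSV dialect.

    Raises
    ------
    TopographyFormatError
        Empty file, missing required columns or metadata keys.
    TopographyValidationError
        The parsed grid violates a structural invariant.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if ":" in stripped:
                    key, _, value = stripped.partition(":")
                    meta[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    if not any(l.strip() for l in body_lines):
        raise TopographyFormatError(f"{path}: no data rows")
    for key in ("map_id", "eye", "visit"):
        if key not in meta:
            raise TopographyFormatError(f"{path}: missing '# {key}:' metadata header")

    df = pd.read_csv(io.StringIO("".join(body_lines)))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TopographyFormatError(f"{path}: missing required columns {missing}")

    angles: list[float] = []
    samples: list[MeridianSamples] = []
    for a, sub in df.groupby("meridian_deg", sort=True):
        angles.append(float(a))
        kwargs = {}
        for col in OPTIONAL_COLUMNS:
            if col in sub.columns and sub[col].notna().any():
                kwargs[col] = sub[col].to_numpy(dtype=float)
        samples.append(
            MeridianSamples(
                radial_mm=sub["radial_mm"].to_numpy(dtype=float),
                sag_mm=sub["sag_mm"].to_numpy(dtype=float),
                axial_radius_mm=sub["axial_radius_mm"].to_numpy(dtype=float),
                **kwargs,
            )
        )
    extra = {
        k: v for k, v in meta.items() if k not in ("map_id", "eye", "visit")
    }
    grid = TopographyGrid(
        map_id=meta["map_id"],
        eye=meta["eye"],
        visit=meta["visit"],
        meridian_angles=np.array(angles),
        samples=samples,
        meta=extra,
    )
    _check(grid)
    return grid


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def _fmt_angle(x: float) -> str:
    # full precision: the uniform-spacing invariant is checked to 1e-9 deg,
    # which 10 significant digits cannot preserve for e.g. 360/7
    return f"{x:.17g}"


def write_grid(grid: TopographyGrid, path: str | Path) -> None:
    """Serialise a validated grid to the long-CSV dialect (10 sig. digits)."""
    _check(grid)
    path = Path(path)
    has_tan = any(s.tangential_radius_mm is not None for s in grid.samples)
    has_slope = any(s.slope is not None for s in grid.samples)
    cols = list(REQUIRED_COLUMNS)
    if has_tan:
        cols.append("tangential_radius_mm")
    if has_slope:
        cols.append("slope")
    lines = [f"# map_id: {grid.map_id}", f"# eye: {grid.eye}", f"# visit: {grid.visit}"]
    for k, v in grid.meta.items():
        lines.append(f"# {k}: {v}")
    lines.append(",".join(cols))
    for a, s in zip(grid.meridian_angles, grid.samples):
        for i in range(s.n):
            row = [_fmt_angle(a), _fmt(s.radial_mm[i]), _fmt(s.sag_mm[i]),
                   _fmt(s.axial_radius_mm[i])]
            if has_tan:
                row.append(
                    _fmt(s.tangential_radius_mm[i])
                    if s.tangential_radius_mm is not None else ""
                )
            if has_slope:
                row.append(_fmt(s.slope[i]) if s.slope is not None else "")
            lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
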