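"""Population geography and climate distances.

Provenance sites are given as degree-minute coordinates plus elevation.
Between-site separation is the straight-line (chord) distance between the
two points embedded in 3-D space on a sphere of radius R inflated by each
site's elevation:

    x = (h + R) cos(lat) cos(lon)
    y = (h + R) cos(lat) sin(lon)
    z = (h + R) sin(lat)
    L = sqrt((x1-x2)^2 + (y1-y2)^2 + (z1-z2)^2)

This chord runs through the Earth, so it is a lower bound on the
great-circle arc; the two converge as the separation shrinks.  Climate
dissimilarity between two sites is the absolute difference of a climate
variable's long-term mean, one matrix per variable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distmat import DistanceMatrix

__all__ = [
    "EARTH_RADIUS_M",
    "PopulationMeta",
    "parse_dms",
    "chord_distance",
    "geographic_distance_matrix",
    "climate_distance_matrices",
    "read_population_meta",
]

EARTH_RADIUS_M = 6_371_000.0

# degrees-minutes(-seconds) with optional hemisphere, tolerant of spaces and
# of ASCII quote stand-ins for the prime glyphs
_DMS_RE = re.compile(
    r"""^\s*([NSEW])?\s*
        (\d+(?:\.\d+)?)\s*[°d]\s*
        (?:(\d+(?:\.\d+)?)\s*[′'m]\s*)?
        (?:(\d+(?:\.\d+)?)\s*[″"s]\s*)?
        ([NSEW])?\s*$""",
    re.VERBOSE,
)


def parse_dms(text: str) -> float:
    """Parse ``25°19′`` / ``109°48′34″ E`` / ``S 3°12′`` to decimal degrees."""
    m = _DMS_RE.match(str(text))
    if m is None:
        raise ValueError(f"malformed coordinate: {text!r}")
    pre, deg, minute, sec, post = m.groups()
    if pre and post:
        raise ValueError(f"two hemisphere letters in {text!r}")
    minute = float(minute) if minute else 0.0
    sec = float(sec) if sec else 0.0
    if minute >= 60 or sec >= 60:
        raise ValueError(f"minutes/seconds out of range in {text!r}")
    value = float(deg) + minute / 60.0 + sec / 3600.0
    hemi = pre or post
    if hemi in ("S", "W"):
        value = -value
    return value


@dataclass(frozen=True)
class PopulationMeta:
    """One provenance site: label, decimal-degree coordinates, elevation (m)."""

    population: str
    latitude: float
    longitude: float
    elevation: float = 0.0

    def __post_init__(self):
        if not abs(self.latitude) <= 90:
            raise ValueError(f"latitude {self.latitude} out of range")
        if not abs(self.longitude) <= 180:
            raise ValueError(f"longitude {self.longitude} out of range")
        if not np.isfinite(self.elevation):
            raise ValueError("elevation must be finite")

    def xyz(self, radius: float = EARTH_RADIUS_M) -> np.ndarray:
        la = np.radians(self.latitude)
        lo = np.radians(self.longitude)
        r = self.elevation + radius
        return np.array(
            [r * np.cos(la) * np.cos(lo), r * np.cos(la) * np.sin(lo), r * np.sin(la)]
        )


def chord_distance(p1: PopulationMeta, p2: PopulationMeta,
                   radius: float = EARTH_RADIUS_M) -> float:
    """Straight-line distance in meters between two embedded sites."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return float(np.linalg.norm(p1.xyz(radius) - p2.xyz(radius)))


def geographic_distance_matrix(meta, radius: float = EARTH_RADIUS_M,
                               log: bool = False):
    """All pairwise chord distances, optionally natural-log transformed.

    ``log=True`` returns the companion ln-distance matrix used for
    isolation-by-distance regressions; coincident sites produce ln(0)
    cells which come back masked, not -inf.
    """
    meta = list(meta)
    if len(meta) < 2:
        raise ValueError("need at least two populations")
    pts = np.stack([m.xyz(radius) for m in meta])
    diff = pts[:, None, :] - pts[None, :, :]
    vals = np.sqrt((diff ** 2).sum(axis=2))
    np.fill_diagonal(vals, 0.0)
    dm = DistanceMatrix([m.population for m in meta], vals)
    if log:
        return dm.map(np.log)
    return dm


def climate_distance_matrices(climate: pd.DataFrame) -> dict[str, DistanceMatrix]:
    """One |v_i - v_j| matrix per climate variable.

    ``climate`` is indexed by population (or has a ``population`` column)
    with one numeric column per variable; any missing cell is an error
    naming the population and variable.
    """
    df = climate.copy()
    if "population" in df.columns:
        df = df.set_index("population")
    df.index = df.index.astype(str)
    if df.shape[1] == 0:
        raise ValueError("climate table has no variables")
    out = {}
    for var in df.columns:
        col = pd.to_numeric(df[var], errors="coerce")
        if col.isna().any():
            bad = df.index[col.isna()][0]
            raise ValueError(f"missing climate value: population {bad}, variable {var}")
        v = col.to_numpy(dtype=float)
        out[var] = DistanceMatrix(list(df.index), np.abs(v[:, None] - v[None, :]))
    return out


def read_population_meta(path) -> list[PopulationMeta]:
    """Read a metadata CSV with columns population, latitude, longitude, elevation.

    Coordinates may be decimal degrees or degree-minute(-second) strings;
    the format is auto-detected per cell.
    """
    df = pd.read_csv(path, dtype=str, comment="#")
    cols = {c.lower(): c for c in df.columns}
    for need in ("population", "latitude", "longitude"):
        if need not in cols:
            raise ValueError(f"metadata is missing a {need} column")
    out = []
    for _, row in df.iterrows():
        out.append(
            PopulationMeta(
                population=str(row[cols["population"]]),
                latitude=_coord(row[cols["latitude"]]),
                longitude=_coord(row[cols["longitude"]]),
                elevation=float(row[cols["elevation"]]) if "elevation" in cols else 0.0,
            )
        )
    return out


def _coord(text) -> float:
    try:
        return float(text)
    except (TypeError, ValueError):
        return parse_dms(text)
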