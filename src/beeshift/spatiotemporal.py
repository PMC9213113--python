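"""Grid sites, 20-year eras, 5-year intervals, and convex-hull range masks.

Occurrence coordinates are projected with an equal-area Albers conic so
that "100 x 100 km" grid cells really do enclose equal area across the
continent, then binned into square cells with a half-open convention.
Years are binned into six 20-year eras (1901-1920, ..., 2001-2020),
each split into four 5-year intervals -- the repeat-visit unit that
lets an occupancy model separate detection from occupancy.

Each species is modelled only at sites plausibly inside its range:
the convex hull (in projected coordinates) of all sites where it was
ever recorded, with cell centroids on the hull boundary counted as
inside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint, Point

from .records import OccurrenceRecord

# ---------------------------------------------------------------------------
# Projection


@dataclass(frozen=True)
class AlbersEqualArea:
    """Spherical Albers equal-area conic projection (forward + inverse).

    Defaults are the customary North America parameters: standard
    parallels 20N and 60N, origin at 40N, 96W, on the authalic sphere.
    Spherical rather than ellipsoidal formulas keep the transform
    dependency-free; the difference (<0.5%) is immaterial at 50-250 km
    cell sizes.
    """

    lat_1: float = 20.0
    lat_2: float = 60.0
    lat_0: float = 40.0
    lon_0: float = -96.0
    radius: float = 6_371_007.2  # authalic sphere, metres

    @property
    def identifier(self) -> str:
        return (
            f"albers-sph:+lat_1={self.lat_1}+lat_2={self.lat_2}"
            f"+lat_0={self.lat_0}+lon_0={self.lon_0}+R={self.radius}"
        )

    def _constants(self) -> tuple[float, float, float]:
        phi1, phi2 = math.radians(self.lat_1), math.radians(self.lat_2)
        n = (math.sin(phi1) + math.sin(phi2)) / 2.0
        c = math.cos(phi1) ** 2 + 2.0 * n * math.sin(phi1)
        rho0 = self.radius * math.sqrt(c - 2.0 * n * math.sin(math.radians(self.lat_0))) / n
        return n, c, rho0

    def forward(self, lon, lat):
        """(lon, lat) degrees -> projected (x, y) metres. Vectorized."""
        n, c, rho0 = self._constants()
        lam = np.radians(np.asarray(lon, dtype=float) - self.lon_0)
        phi = np.radians(np.asarray(lat, dtype=float))
        rho = self.radius * np.sqrt(c - 2.0 * n * np.sin(phi)) / n
        theta = n * lam
        x = rho * np.sin(theta)
        y = rho0 - rho * np.cos(theta)
        return x, y

    def inverse(self, x, y):
        """Projected (x, y) metres -> (lon, lat) degrees. Vectorized."""
        n, c, rho0 = self._constants()
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rho = np.hypot(x, rho0 - y)
        theta = np.arctan2(x, rho0 - y)
        phi = np.arcsin((c - (rho * n / self.radius) ** 2) / (2.0 * n))
        lam = theta / n
        return np.degrees(lam) + self.lon_0, np.degrees(phi)


# ---------------------------------------------------------------------------
# Site grid

#: Default grid origin in projected metres; far enough southwest that all
#: North American cells get non-negative (col, row) indices.
DEFAULT_ORIGIN = (-5_000_000.0, -4_000_000.0)


@dataclass
class SiteGrid:
    """Square grid over projected North America.

    Cell membership uses half-open intervals ``[edge, edge + cell_size)``
    in both axes, so a point exactly on a cell's upper edge belongs to
    the next cell.
    """

    cell_size: float = 100_000.0
    projection: AlbersEqualArea = field(default_factory=AlbersEqualArea)
    origin: tuple[float, float] = DEFAULT_ORIGIN
    cells: set[tuple[int, int]] = field(default_factory=set)

    def cell_of_xy(self, x, y):
        """Projected coordinates -> integer (col, row) cell indices."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.origin[1]) / self.cell_size).astype(int)
        return col, row

    def cell_of_lonlat(self, lon, lat):
        return self.cell_of_xy(*self.projection.forward(lon, lat))

    def centroid_xy(self, cell: tuple[int, int]) -> tuple[float, float]:
        col, row = cell
        return (
            self.origin[0] + (col + 0.5) * self.cell_size,
            self.origin[1] + (row + 0.5) * self.cell_size,
        )

    def centroid_lonlat(self, cell: tuple[int, int]) -> tuple[float, float]:
        lon, lat = self.projection.inverse(*self.centroid_xy(cell))
        return float(lon), float(lat)


def assign_site(record: OccurrenceRecord, grid: SiteGrid) -> tuple[int, int]:
    """Map a record to its grid cell; registers the cell on the grid."""
    x, y = grid.projection.forward(record.longitude, record.latitude)
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError(
            f"projection failure for ({record.longitude}, {record.latitude})"
        )
    col, row = grid.cell_of_xy(x, y)
    cell = (int(col), int(row))
    grid.cells.add(cell)
    return cell


# ---------------------------------------------------------------------------
# Eras and intervals

ERA_START_DEFAULT = 1901
ERA_LENGTH = 20
INTERVAL_LENGTH = 5
N_INTERVALS = ERA_LENGTH // INTERVAL_LENGTH  # 4


@dataclass(frozen=True)
class EraInterval:
    era: int  # 1-based
    interval: int  # 1-based within era


def assign_era_interval(
    year: int, *, era_start: int = ERA_START_DEFAULT, n_eras: int = 6
) -> EraInterval:
    """Bin a year into its (era, interval).

    With the default 1901 start: era = floor((year-1901)/20)+1 in 1..6,
    interval = floor(((year-1901) mod 20)/5)+1 in 1..4.
    """
    era_end = era_start + n_eras * ERA_LENGTH - 1
    if not (era_start <= year <= era_end):
        raise ValueError(f"year {year} outside study period {era_start}-{era_end}")
    offset = year - era_start
    era = offset // ERA_LENGTH + 1
    interval = (offset % ERA_LENGTH) // INTERVAL_LENGTH + 1
    return EraInterval(era=int(era), interval=int(interval))


# ---------------------------------------------------------------------------
# Range masks


@dataclass
class RangeMask:
    """Sites inside a species' convex-hull range."""

    species: str
    included_sites: set[tuple[int, int]]


def build_range_mask(
    species: str,
    occupied_sites: set[tuple[int, int]],
    grid: SiteGrid,
    *,
    candidate_sites: set[tuple[int, int]] | None = None,
) -> RangeMask:
    """Convex hull of the species' occupied site centroids.

    ``included_sites`` is every candidate site (default: all registered
    grid cells) whose centroid lies inside or on the hull.  With fewer
    than three occupied sites, or all centroids collinear, the hull is
    degenerate and the mask falls back to exactly the occupied sites.
    Occupied sites are always included.
    """
    if not occupied_sites:
        raise ValueError(f"no occupied sites for {species}")
    candidates = candidate_sites if candidate_sites is not None else grid.cells
    pts = [grid.centroid_xy(c) for c in occupied_sites]
    hull = MultiPoint(pts).convex_hull
    if hull.geom_type != "Polygon":  # point or line: degenerate
        return RangeMask(species=species, included_sites=set(occupied_sites))
    included = {
        c for c in candidates if hull.covers(Point(*grid.centroid_xy(c)))
    }
    included |= set(occupied_sites)
    return RangeMask(species=species, included_sites=included)
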