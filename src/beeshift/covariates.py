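"""Per-site, per-era environmental predictors.

Three predictors drive the environmental occupancy model:

* mean monthly maximum temperature (degC) over all months of an era,
* mean monthly precipitation (kg m-2 month-1) likewise,
* a floral-resource score FR: expert seasonal floral suitabilities of
  crop classes are area-averaged into land-use-category scores, summed
  over spring/summer/autumn, and then composition-averaged within each
  site x era.  Temporal variation in FR comes only from land-use
  composition changing between eras; the category score table itself is
  era-invariant.

Covariates are standardized (z-scored with the population sd over the
modelled site x era set) before fitting, and the constants are kept so
model output can be mapped back to natural units (e.g. a thermal
optimum in degC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEASONS = ("spring", "summer", "autumn")


# ---------------------------------------------------------------------------
# Climate aggregation


def aggregate_climate(
    gridded_series: pd.DataFrame,
    site_cells: dict,
    era_of_year,
    *,
    n_sites: int | None = None,
    n_eras: int | None = None,
) -> np.ndarray:
    """Aggregate a monthly climate series to site x era means.

    Parameters
    ----------
    gridded_series
        Long-format frame with columns ``cell``, ``year``, ``month``,
        ``value`` (one row per climate cell per calendar month).
    site_cells
        Mapping ``site index -> list of climate cell ids`` overlapping
        that site.  Cells are weighted equally within a site.
    era_of_year
        Callable ``year -> era index (0-based)``; years mapping to
        ``None`` are ignored.

    Returns
    -------
    ndarray of shape (n_sites, n_eras): entry (j, k) is the mean over
    cells of each cell's mean monthly value across era k.  Raises if any
    site x era has no coverage.
    """
    df = gridded_series.copy()
    df["era"] = [era_of_year(y) for y in df["year"]]
    df = df[df["era"].notna()]
    # per-cell per-era mean first, then equal-weight mean over cells
    cell_era = df.groupby(["cell", "era"])["value"].mean()

    sites = sorted(site_cells)
    n_sites = n_sites or len(sites)
    n_eras = n_eras or int(df["era"].max()) + 1
    out = np.full((n_sites, n_eras), np.nan)
    missing = []
    for j, site in enumerate(sites):
        for k in range(n_eras):
            vals = [
                cell_era.get((cell, k), np.nan) for cell in site_cells[site]
            ]
            vals = [v for v in vals if not np.isnan(v)]
            if not vals:
                missing.append((site, k))
            else:
                out[j, k] = float(np.mean(vals))
    if missing:
        raise ValueError(f"no climate coverage for site/era pairs: {missing[:10]}")
    return out


# ---------------------------------------------------------------------------
# Floral resources


@dataclass
class FloralScoreTable:
    """Season-resolved floral scores per land-use category.

    ``scores`` is indexed by category with columns spring/summer/autumn
    and ``total`` = their sum.
    """

    scores: pd.DataFrame

    def total(self, category: str) -> float:
        if category not in self.scores.index:
            raise KeyError(f"unknown land-use category: {category!r}")
        return float(self.scores.loc[category, "total"])


def derive_category_scores(
    overlap: pd.DataFrame, crop_scores: pd.DataFrame
) -> FloralScoreTable:
    """Area-weighted seasonal floral scores per land-use category.

    Parameters
    ----------
    overlap
        Rows of ``(landuse_category, crop_class, area)`` giving, for each
        coarse land-use category, the geographic overlap area with each
        finer crop class.
    crop_scores
        Indexed by ``crop_class`` with columns ``spring, summer, autumn``
        (non-negative expert floral suitability scores).

    The category score for a season is the overlap-area-weighted mean of
    the crop-class scores; ``total`` sums the three seasons.
    """
    if (overlap["area"] < 0).any():
        raise ValueError("negative overlap area")
    unknown = set(overlap["crop_class"]) - set(crop_scores.index)
    if unknown:
        raise KeyError(f"crop classes without scores: {sorted(unknown)}")
    rows = {}
    for cat, grp in overlap.groupby("landuse_category"):
        total_area = grp["area"].sum()
        if total_area <= 0:
            raise ValueError(f"category {cat!r} has zero total overlap area")
        w = grp["area"].to_numpy() / total_area
        sc = crop_scores.loc[grp["crop_class"], list(SEASONS)].to_numpy()
        rows[cat] = w @ sc
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(SEASONS))
    table["total"] = table[list(SEASONS)].sum(axis=1)
    return FloralScoreTable(scores=table)


def site_floral_score(composition: dict, table: FloralScoreTable) -> float:
    """FR for one site x era: composition-weighted mean of category totals.

    ``composition`` maps category -> areal fraction; fractions must be
    non-negative and sum to 1 (tolerance 1e-6).
    """
    fracs = np.array(list(composition.values()), dtype=float)
    if (fracs < 0).any():
        raise ValueError("negative composition fraction")
    if abs(fracs.sum() - 1.0) > 1e-6:
        raise ValueError(f"composition fractions sum to {fracs.sum()}, not 1")
    return float(sum(f * table.total(cat) for cat, f in composition.items()))


# ---------------------------------------------------------------------------
# Standardization


def standardize(matrix: np.ndarray, mask: np.ndarray | None = None):
    """Z-score a site x era matrix over its modelled entries.

    Uses the population standard deviation.  ``mask`` (optional boolean
    array, True = modelled) restricts which entries define the mean/sd;
    the transform itself is applied everywhere.

    Returns ``(z, mean, sd)``; raises on zero sd.
    """
    matrix = np.asarray(matrix, dtype=float)
    vals = matrix[mask] if mask is not None else matrix
    mean = float(np.mean(vals))
    sd = float(np.std(vals))
    if sd <= 0.0:
        raise ValueError("cannot standardize a constant matrix (sd = 0)")
    return (matrix - mean) / sd, mean, sd


def destandardize(z, mean: float, sd: float):
    return np.asarray(z) * sd + mean


@dataclass
class EraCovariates:
    """Site x era covariate matrices, raw and standardized.

    ``temp`` in degC (mean monthly maximum), ``precip`` in kg m-2
    month-1, ``floral`` in FR units.  ``temp_z``/``precip_z``/
    ``floral_z`` are the standardized copies actually handed to the
    model; ``constants`` maps variable name -> (mean, sd).
    """

    temp: np.ndarray
    precip: np.ndarray
    floral: np.ndarray
    temp_z: np.ndarray | None = None
    precip_z: np.ndarray | None = None
    floral_z: np.ndarray | None = None
    constants: dict = field(default_factory=dict)

    VARIABLES = ("temp", "precip", "floral")

    @property
    def n_sites(self) -> int:
        return self.temp.shape[0]

    @property
    def n_eras(self) -> int:
        return self.temp.shape[1]

    def standardized(self, mask: np.ndarray | None = None) -> "EraCovariates":
        """Return a copy with z-scored matrices and saved constants."""
        if (self.floral < 0).any():
            raise ValueError("floral scores must be non-negative")
        out = EraCovariates(temp=self.temp, precip=self.precip, floral=self.floral)
        for name in self.VARIABLES:
            z, mean, sd = standardize(getattr(self, name), mask)
            setattr(out, f"{name}_z", z)
            out.constants[name] = (mean, sd)
        return out

    def require_standardized(self) -> "EraCovariates":
        if self.temp_z is None:
            return self.standardized()
        return self

    def subset_sites(self, site_idx: np.ndarray) -> "EraCovariates":
        """Restrict to a subset of sites (re-standardizing from raw)."""
        return EraCovariates(
            temp=self.temp[site_idx],
            precip=self.precip[site_idx],
            floral=self.floral[site_idx],
        ).standardized()

    def to_frame(self) -> pd.DataFrame:
        """Long-format (site, era, temp, precip, floral) table."""
        j, k = np.meshgrid(
            np.arange(self.n_sites), np.arange(self.n_eras), indexing="ij"
        )
        return pd.DataFrame(
            {
                "site": j.ravel(),
                "era": k.ravel(),
                "temp": self.temp.ravel(),
                "precip": self.precip.ravel(),
                "floral": self.floral.ravel(),
            }
        )


def era_index_z(n_eras: int) -> np.ndarray:
    """Standardized era index (population z-score of 1..n_eras).

    This is the time axis of the era model: a logit-linear trend on a
    centred, unit-variance era number, so the community trend
    coefficient is comparable in scale to the environmental slopes.
    """
    idx = np.arange(1, n_eras + 1, dtype=float)
    return (idx - idx.mean()) / idx.std()
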