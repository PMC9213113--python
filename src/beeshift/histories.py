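"""Detection/non-detection histories with inferred zeros.

Presence-only records carry no explicit absences.  The key inferential
move: if *any* bumblebee was recorded at a site during a 5-year
interval, someone was there collecting, so every other species whose
range plausibly covers that site gets an inferred non-detection (0) for
that interval.  Site x interval combinations with no records of any
species stay missing (NA), as do all intervals at sites outside a
species' range — NAs are represented by a boolean ``observed`` mask,
never by a sentinel value, so likelihood code cannot silently treat a
missing interval as a zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .spatiotemporal import RangeMask

logger = logging.getLogger(__name__)


@dataclass
class DetectionData:
    """Species x site x era x interval detection array plus masks.

    Attributes
    ----------
    y : int8 array (S, J, K, T)
        1 = detected, 0 = inferred non-detection; only meaningful where
        ``observed`` is True.
    observed : bool array (S, J, K, T)
        True where a detection/non-detection datum exists: the interval
        was visited and the site is in the species' range.
    visited : bool array (J, K, T)
        True where >=1 record of any species exists.
    range_mask : bool array (S, J)
        True where site j is inside species s' range.
    record_counts : int array (J, K, T)
        Raw record tallies (all species pooled), used by site-retention
        filters and effort summaries.
    species, sites : label lists for the S and J axes.
    """

    y: np.ndarray
    observed: np.ndarray
    visited: np.ndarray
    range_mask: np.ndarray
    record_counts: np.ndarray
    species: list
    sites: list

    @property
    def n_species(self) -> int:
        return self.y.shape[0]

    @property
    def n_sites(self) -> int:
        return self.y.shape[1]

    @property
    def n_eras(self) -> int:
        return self.y.shape[2]

    @property
    def n_intervals(self) -> int:
        return self.y.shape[3]

    def validate(self) -> None:
        """Assert the structural invariants; raises AssertionError."""
        S, J, K, T = self.y.shape
        assert self.observed.shape == (S, J, K, T)
        assert self.visited.shape == (J, K, T)
        assert self.range_mask.shape == (S, J)
        expected_observed = (
            self.visited[None, :, :, :] & self.range_mask[:, :, None, None]
        )
        assert np.array_equal(self.observed, expected_observed), (
            "observed mask must equal visited AND in-range"
        )
        assert np.all(np.isin(self.y[self.observed], (0, 1)))
        assert not np.any(self.y[~self.observed]), "y must be 0 outside the mask"
        assert np.all(
            self.visited[None] | ~(self.y.astype(bool))
        ), "y = 1 requires a visit"

    def detections_per_site_era(self) -> np.ndarray:
        """(S, J, K) count of detected intervals per species-site-era."""
        return (self.y * self.observed).sum(axis=3)

    def visits_per_site_era(self) -> np.ndarray:
        """(J, K) number of visited intervals."""
        return self.visited.sum(axis=2)

    def summary_report(self) -> dict:
        """Descriptive numbers for comparison with published datasets."""
        visited_se = self.visits_per_site_era() > 0
        n_visited_se = int(visited_se.sum())
        det = self.detections_per_site_era()
        species_per_se = (det > 0).sum(axis=0)
        return {
            "n_records": int(self.record_counts.sum()),
            "n_species": self.n_species,
            "n_sites": self.n_sites,
            "n_species_site_interval_detections": int(self.y[self.observed].sum()),
            "mean_visits_per_site_era": float(
                self.visits_per_site_era()[visited_se].mean()
            ) if n_visited_se else 0.0,
            "mean_detections_per_site_era": float(
                det.sum(axis=0)[visited_se].mean()
            ) if n_visited_se else 0.0,
            "mean_species_per_site_era": float(
                species_per_se[visited_se].mean()
            ) if n_visited_se else 0.0,
        }

    def to_dataset(self):
        """Pack into an :class:`xarray.Dataset` for NetCDF-style output."""
        import xarray as xr

        site_labels = [str(s) for s in self.sites]
        return xr.Dataset(
            {
                "y": (("species", "site", "era", "interval"), self.y),
                "observed": (("species", "site", "era", "interval"), self.observed),
                "visited": (("site", "era", "interval"), self.visited),
                "range_mask": (("species", "site"), self.range_mask),
                "record_counts": (("site", "era", "interval"), self.record_counts),
            },
            coords={
                "species": self.species,
                "site": site_labels,
                "era": np.arange(1, self.n_eras + 1),
                "interval": np.arange(1, self.n_intervals + 1),
            },
        )


def build_visits(
    assignments: pd.DataFrame,
    sites: list,
    n_eras: int,
    n_intervals: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Visit mask and record tallies from assigned records.

    ``assignments`` has one row per record with columns ``site``
    (matching entries of ``sites``), ``era`` and ``interval`` (1-based).
    Returns ``(visited, record_counts)``; a site x era x interval is
    visited iff >=1 record of any species exists there.
    """
    J = len(sites)
    site_pos = {s: j for j, s in enumerate(sites)}
    counts = np.zeros((J, n_eras, n_intervals), dtype=np.int64)
    if len(assignments):
        jj = assignments["site"].map(site_pos).to_numpy()
        kk = assignments["era"].to_numpy() - 1
        tt = assignments["interval"].to_numpy() - 1
        np.add.at(counts, (jj, kk, tt), 1)
    return counts > 0, counts


def build_histories(
    assignments: pd.DataFrame,
    visited: np.ndarray,
    record_counts: np.ndarray,
    range_masks: dict[str, RangeMask],
    species: list[str],
    sites: list,
) -> DetectionData:
    """Assemble the 4-D detection array.

    ``assignments`` rows carry ``species, site, era, interval``; order is
    irrelevant (the construction is permutation-invariant).  A record of
    a species at a site outside its own range mask violates the range
    construction and raises.
    """
    S, J = len(species), len(sites)
    K, T = visited.shape[1], visited.shape[2]
    species_pos = {s: i for i, s in enumerate(species)}
    site_pos = {s: j for j, s in enumerate(sites)}

    range_arr = np.zeros((S, J), dtype=bool)
    for i, sp in enumerate(species):
        for cell in range_masks[sp].included_sites:
            j = site_pos.get(cell)
            if j is not None:
                range_arr[i, j] = True

    y = np.zeros((S, J, K, T), dtype=np.int8)
    if len(assignments):
        ii = assignments["species"].map(species_pos).to_numpy()
        jj = assignments["site"].map(site_pos).to_numpy()
        kk = assignments["era"].to_numpy() - 1
        tt = assignments["interval"].to_numpy() - 1
        if not range_arr[ii, jj].all():
            bad = ~range_arr[ii, jj]
            raise AssertionError(
                "records at sites outside their species' own range mask: "
                f"{assignments[bad].head()}"
            )
        y[ii, jj, kk, tt] = 1

    observed = visited[None, :, :, :] & range_arr[:, :, None, None]
    y &= observed  # paranoia: no data outside the mask
    data = DetectionData(
        y=y,
        observed=observed,
        visited=visited,
        range_mask=range_arr,
        record_counts=record_counts,
        species=list(species),
        sites=list(sites),
    )
    ones = int(y[observed].sum())
    zeros = int(observed.sum()) - ones
    nas = int(np.prod(y.shape)) - int(observed.sum())
    logger.info(
        "histories: %d detections, %d inferred non-detections, %d NA", ones, zeros, nas
    )
    return data


def filter_sites(
    data: DetectionData,
    mode: str = "default",
    *,
    min_records_per_era: int = 5,
) -> DetectionData:
    """Site-retention filters.

    ``default``
        keep site j iff it has records in >=2 eras AND at least one era
        has records in >=2 distinct 5-year intervals (so that repeat
        visits within an era exist somewhere to inform detection).
    ``strict``
        keep site j iff *every* era has >= ``min_records_per_era``
        records (default 5).
    ``none``
        keep everything.

    Subsets every array to the kept sites; raises if nothing survives.
    """
    if mode == "none":
        return data
    recs_per_era = data.record_counts.sum(axis=2)  # (J, K)
    intervals_with_recs = (data.record_counts > 0).sum(axis=2)  # (J, K)
    if mode == "default":
        keep = (recs_per_era > 0).sum(axis=1) >= 2
        keep &= (intervals_with_recs >= 2).any(axis=1)
    elif mode == "strict":
        keep = (recs_per_era >= min_records_per_era).all(axis=1)
    else:
        raise ValueError(f"unknown site filter mode {mode!r}")
    if not keep.any():
        raise ValueError(f"site filter {mode!r} removed every site")
    logger.info(
        "filter_sites(%s): kept %d / %d sites", mode, int(keep.sum()), data.n_sites
    )
    idx = np.flatnonzero(keep)
    return replace(
        data,
        y=data.y[:, idx],
        observed=data.observed[:, idx],
        visited=data.visited[idx],
        range_mask=data.range_mask[:, idx],
        record_counts=data.record_counts[idx],
        sites=[data.sites[j] for j in idx],
    )
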