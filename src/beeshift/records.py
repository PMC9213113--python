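"""Loading, cleaning, and filtering of bumblebee occurrence records.

Occurrence databases aggregated from museum collections, surveys and
citizen-science projects arrive as delimited text with one row per
specimen.  This module turns such tables into clean
:class:`OccurrenceRecord` lists: rows with unparseable coordinates or
years become *rejects* (kept, with a reason, for audit), records are
restricted to the study window and region, poorly covered species are
dropped, and exact re-reports of the same collection event are
collapsed to a single record.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from shapely.geometry import Point, Polygon, box
from shapely.prepared import prep

logger = logging.getLogger(__name__)

#: Species excluded by default: poor data coverage / newly described.
DEFAULT_EXCLUDED_SPECIES = ("Bombus cockerelli", "Bombus kluanensis")

#: Generous continental North America bounding box (lon/lat, WGS84),
#: spanning Mexico through arctic Canada and Alaska.
DEFAULT_BOUNDING_REGION: Polygon = box(-170.0, 14.0, -52.0, 83.0)

#: Coordinate rounding used in the deduplication key, in degrees
#: (1e-6 deg is roughly 0.1 m — far below any georeferencing precision).
DEDUP_COORD_PRECISION = 1e-6

_YEAR_RE = re.compile(r"^\d{4}$")


@dataclass(frozen=True)
class OccurrenceRecord:
    """One cleaned specimen/observation row.

    Attributes
    ----------
    species : canonical binomial, e.g. ``"Bombus impatiens"``.
    longitude, latitude : decimal degrees, WGS84.
    year : 4-digit calendar year.
    observer : collector/observer identifier; may be empty.
    source_id : opaque provenance string (row id, catalogue number, ...).
    date : full ISO date string when the source provides one, else None.
    """

    species: str
    longitude: float
    latitude: float
    year: int
    observer: str = ""
    source_id: str = ""
    date: str | None = None

    def __post_init__(self) -> None:
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not (1000 <= self.year <= 9999):
            raise ValueError(f"year {self.year} is not a 4-digit integer")


class LoadResult(NamedTuple):
    records: list[OccurrenceRecord]
    rejects: pd.DataFrame  # original columns plus a "reason" column


def canonicalize_species(name: str) -> str:
    """Trim, collapse internal whitespace, and case-fold a binomial.

    ``"  BOMBUS   Impatiens "`` -> ``"Bombus impatiens"``.  No synonym
    resolution is attempted.
    """
    parts = str(name).strip().split()
    if not parts:
        return ""
    genus = parts[0].capitalize()
    rest = [p.lower() for p in parts[1:]]
    return " ".join([genus, *rest])


#: canonical field -> (required, description)
SCHEMA_FIELDS = {
    "species": True,
    "longitude": True,
    "latitude": True,
    "year": True,
    "observer": False,
    "source_id": False,
    "date": False,
}


def load_records(
    path: str | Path,
    schema_config: Mapping[str, str],
    *,
    delimiter: str | None = None,
) -> LoadResult:
    """Read an occurrence table and build records row by row.

    Parameters
    ----------
    path
        Delimited text file (CSV by default; TSV inferred from suffix or
        forced with ``delimiter``).
    schema_config
        Mapping from canonical field names (``species``, ``longitude``,
        ``latitude``, ``year``, optionally ``observer``, ``source_id``,
        ``date``) to the column names used in the file.

    Returns
    -------
    LoadResult
        ``records`` holds one :class:`OccurrenceRecord` per parseable
        row, in file order; ``rejects`` holds the unparseable rows with
        a ``reason`` column.  ``len(records) + len(rejects)`` always
        equals the number of data rows in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"occurrence table not found: {path}")
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)

    for canonical, required in SCHEMA_FIELDS.items():
        col = schema_config.get(canonical)
        if required and col is None:
            raise KeyError(f"schema_config missing required field {canonical!r}")
        if col is not None and col not in df.columns:
            raise KeyError(f"mapped column {col!r} (for {canonical!r}) not in file")

    records: list[OccurrenceRecord] = []
    reject_rows: list[int] = []
    reject_reasons: list[str] = []

    col = {k: schema_config.get(k) for k in SCHEMA_FIELDS}
    for idx, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        reason = None
        lon = lat = None
        year = None
        try:
            lon = float(rowd[col["longitude"]])
            lat = float(rowd[col["latitude"]])
        except (TypeError, ValueError):
            reason = "missing coordinate"
        else:
            if pd.isna(lon) or pd.isna(lat):
                reason = "missing coordinate"
            elif not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
                reason = "coordinate out of range"
        if reason is None:
            ystr = str(rowd[col["year"]]).strip()
            if _YEAR_RE.match(ystr):
                year = int(ystr)
            else:
                reason = "unparseable year"
        if reason is None:
            species = canonicalize_species(rowd[col["species"]])
            if not species:
                reason = "missing species"
        if reason is not None:
            reject_rows.append(idx)
            reject_reasons.append(reason)
            continue
        date_val = rowd.get(col["date"], "") if col["date"] else ""
        records.append(
            OccurrenceRecord(
                species=species,
                longitude=lon,
                latitude=lat,
                year=year,
                observer=str(rowd.get(col["observer"], "")) if col["observer"] else "",
                source_id=str(rowd.get(col["source_id"], "")) if col["source_id"] else str(idx),
                date=date_val.strip() or None,
            )
        )

    rejects = df.iloc[reject_rows].copy()
    rejects["reason"] = reject_reasons
    logger.info("loaded %d records, %d rejects from %s", len(records), len(rejects), path)
    return LoadResult(records, rejects)


def filter_records(
    records: Sequence[OccurrenceRecord],
    *,
    excluded_species: Iterable[str] = DEFAULT_EXCLUDED_SPECIES,
    min_year: int = 1901,
    max_year: int = 2020,
    bounding_region: Polygon = DEFAULT_BOUNDING_REGION,
) -> list[OccurrenceRecord]:
    """Apply the record-level retention filters.

    Keeps records with ``min_year <= year <= max_year``, coordinates
    inside (or on the boundary of) ``bounding_region``, and species not
    in ``excluded_species``.  Removal counts per reason are logged at
    INFO level.  Idempotent.
    """
    excluded = {canonicalize_species(s) for s in excluded_species}
    prepared = prep(bounding_region)
    kept: list[OccurrenceRecord] = []
    removed = {"year": 0, "region": 0, "species": 0}
    for r in records:
        if not (min_year <= r.year <= max_year):
            removed["year"] += 1
        elif r.species in excluded:
            removed["species"] += 1
        elif not prepared.intersects(Point(r.longitude, r.latitude)):
            removed["region"] += 1
        else:
            kept.append(r)
    logger.info(
        "filter_records: kept %d / %d (removed: %d outside %d-%d, "
        "%d outside region, %d excluded species)",
        len(kept), len(records), removed["year"], min_year, max_year,
        removed["region"], removed["species"],
    )
    if not kept:
        logger.warning("filter_records produced an empty record set")
    return kept


def _dedup_key(r: OccurrenceRecord, precision: float) -> tuple:
    # Unit of time in the key is the full date when known, else the year.
    when = r.date if r.date else r.year
    return (
        r.species,
        round(r.longitude / precision) * precision,
        round(r.latitude / precision) * precision,
        when,
        r.observer,
    )


def deduplicate(
    records: Sequence[OccurrenceRecord],
    *,
    precision: float = DEDUP_COORD_PRECISION,
) -> list[OccurrenceRecord]:
    """Collapse to unique (species, coordinates, date, observer) rows.

    Coordinates are rounded to ``precision`` degrees before keying, so
    re-entries of the same event that differ only by floating-point noise
    collapse.  The first occurrence of each key is kept; output order
    follows the input.
    """
    seen: set[tuple] = set()
    out: list[OccurrenceRecord] = []
    for r in records:
        key = _dedup_key(r, precision)
        if key not in seen:
            seen.add(key)
            out.append(r)
    logger.info("deduplicate: %d -> %d records", len(records), len(out))
    return out


def write_rejects(rejects: pd.DataFrame, path: str | Path) -> None:
    """Persist the reject table (original columns + reason) as CSV."""
    rejects.to_csv(path, index=False)
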