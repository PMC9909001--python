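"""Natal dispersal distance estimation from band-recovery records.

A record is one banding -> recovery event for an individual bird.  Records
are filtered so that the banding site can be read as the natal site (banded
as nestling/fledgling), the recovery site as a potential breeding site
(recovered mature, in breeding season, inside the breeding range, found
dead, with fine coordinate precision), and the per-species natal dispersal
distance is then summarized as the geometric mean of the banding->recovery
geodesic distances.

Records travel as a pandas DataFrame with the column schema in
:data:`RECORD_COLUMNS`; species metadata as :class:`SpeciesMeta` objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geodesy import GeoPoint, WGS84, vincenty_distance

__all__ = [
    "RECORD_COLUMNS",
    "SpeciesMeta",
    "FilterConfig",
    "FilterAudit",
    "DispersalEstimate",
    "in_breeding_season",
    "in_breeding_bbox",
    "filter_records",
    "estimate_species_dispersal",
    "estimate_all_species",
    "retain_species",
    "read_records_csv",
    "read_meta_csv",
    "estimates_to_frame",
]

#: column schema for band-recovery record tables (one row per event)
RECORD_COLUMNS = [
    "band_id",
    "species",
    "band_date",
    "band_lat",
    "band_lon",
    "age_code",
    "rec_date",
    "rec_lat",
    "rec_lon",
    "rec_condition",
    "precision_code",
]

#: names of the sequential filters, in application order
FILTER_ORDER = [
    "age",        # banded as nestling or fledgling
    "maturity",   # recovered after reaching maturity
    "season",     # banded AND recovered within the breeding season
    "range",      # banded AND recovered inside the breeding-range bbox
    "condition",  # found dead (excludes hunting/banding-station recoveries)
    "precision",  # coordinate uncertainty no coarser than the 1' block
]


@dataclass(frozen=True)
class SpeciesMeta:
    """Per-species filters and ecological predictors.

    Breeding-season bounds are calendar months (1-12) and may wrap around
    the new year (e.g. ``season_start_month=11, season_end_month=2``).  The
    breeding-range bounding box is taken from the extreme points of the
    species' breeding distribution.
    """

    species: str
    season_start_month: int
    season_end_month: int
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    habitat: str = "woodlands"         # woodlands | open | wetlands | coasts
    diet: str = "omnivore"             # herbivore | carnivore | insectivore | omnivore
    foraging: int = 1                  # ordinal 1-5, increasing flight requirement
    population_size: float = np.nan    # breeding individuals, range-wide
    mass: float = np.nan               # g
    migration_distance: float = np.nan  # km, breeding-to-wintering centroids
    range_area: float = np.nan         # km^2
    migratory: bool = False

    HABITATS = frozenset({"woodlands", "open", "wetlands", "coasts"})
    DIETS = frozenset({"herbivore", "carnivore", "insectivore", "omnivore"})

    def __post_init__(self) -> None:
        for m in (self.season_start_month, self.season_end_month):
            if not 1 <= int(m) <= 12:
                raise ValueError(f"{self.species}: month {m} outside 1..12")
        if self.lat_min >= self.lat_max:
            raise ValueError(f"{self.species}: bbox latitudes not ordered")
        if self.habitat not in self.HABITATS:
            raise ValueError(f"{self.species}: unknown habitat {self.habitat!r}")
        if self.diet not in self.DIETS:
            raise ValueError(f"{self.species}: unknown diet {self.diet!r}")
        if not 1 <= int(self.foraging) <= 5:
            raise ValueError(f"{self.species}: foraging {self.foraging} outside 1..5")


@dataclass(frozen=True)
class FilterConfig:
    """Code sets and thresholds driving record filtering.

    Banding-program age/condition encodings are versioned and external, so
    the memberships are configuration, not code.  ``maturity_years`` is the
    minimum elapsed time banding -> recovery for the bird to count as a
    mature adult (the banding scheme's age-at-recovery mechanics are not
    modeled).  ``precision_levels`` orders coordinate-precision classes from
    finest to coarsest; records coarser than ``max_precision`` are dropped.
    ``distance_floor_km`` replaces zero distances (identical rounded
    coordinates) with half the 1' block resolution before logging.
    """

    nestling_codes: frozenset[str] = frozenset({"nestling", "fledgling"})
    found_dead_codes: frozenset[str] = frozenset({"found_dead"})
    precision_levels: tuple[str, ...] = ("exact", "1min", "10min", "degree")
    max_precision: str = "1min"
    maturity_years: float = 1.0
    distance_floor_km: float = 0.926  # half of one arc-minute (1.852 km)
    min_n: int = 5

    def precision_ok(self, code: str) -> bool:
        if code not in self.precision_levels:
            raise ValueError(f"unknown precision code {code!r}")
        return self.precision_levels.index(code) <= self.precision_levels.index(
            self.max_precision
        )


@dataclass
class FilterAudit:
    """Per-filter removal counts, in application order, plus zero-distance flags."""

    input_count: int = 0
    removed: dict[str, int] = field(default_factory=lambda: {f: 0 for f in FILTER_ORDER})
    retained_count: int = 0
    zero_distance_floored: int = 0

    def check(self) -> None:
        assert self.input_count == self.retained_count + sum(self.removed.values())

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class DispersalEstimate:
    """Per-species dispersal summary.

    ``geomean_km`` is exp(mean(ln d)); ``log_se`` is the standard error of
    ln(distance) (NaN for n = 1, where it is undefined); and
    ``mean_recovery_years`` is the mean elapsed time banding -> recovery,
    carried as a covariate against breeding-dispersal contamination.
    """

    species: str
    n: int
    geomean_km: float
    log_se: float
    mean_recovery_years: float


# ---------------------------------------------------------------------------
# predicates

def in_breeding_season(d: date, meta: SpeciesMeta) -> bool:
    """True iff the calendar month of ``d`` lies within the breeding season.

    Season bounds are inclusive months; a season with start > end wraps
    around the new year (Nov-Feb covers months 11, 12, 1, 2).
    """
    m = d.month
    lo, hi = meta.season_start_month, meta.season_end_month
    if lo <= hi:
        return lo <= m <= hi
    return m >= lo or m <= hi


def in_breeding_bbox(p: GeoPoint, meta: SpeciesMeta) -> bool:
    """True iff ``p`` lies inside the species' breeding-range bounding box.

    The longitudinal interval is antimeridian-aware: ``lon_min > lon_max``
    denotes an interval crossing 180 degrees.
    """
    if meta.lon_min == meta.lon_max:
        raise ValueError(f"{meta.species}: degenerate (zero-width) bbox")
    if not meta.lat_min <= p.lat <= meta.lat_max:
        return False
    if meta.lon_min <= meta.lon_max:
        return meta.lon_min <= p.lon <= meta.lon_max
    return p.lon >= meta.lon_min or p.lon <= meta.lon_max


def _elapsed_years(band_date: date, rec_date: date) -> float:
    return (pd.Timestamp(rec_date) - pd.Timestamp(band_date)).days / 365.25


# ---------------------------------------------------------------------------
# filtering

def _require_columns(records: pd.DataFrame) -> None:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"record table missing columns: {missing}")


def filter_records(
    records: pd.DataFrame,
    meta_table: Mapping[str, SpeciesMeta],
    config: FilterConfig = FilterConfig(),
) -> tuple[pd.DataFrame, FilterAudit]:
    """Apply the natal-dispersal filters sequentially and audit removals.

    A record survives iff it passes every filter; the audit attributes each
    removal to the first filter (in :data:`FILTER_ORDER`) that rejects it.
    The retained set is therefore independent of filter order; only the
    attribution depends on it.
    """
    _require_columns(records)
    audit = FilterAudit(input_count=len(records))
    if len(records) == 0:
        return records.copy(), audit

    unknown = sorted(set(records["species"]) - set(meta_table))
    if unknown:
        raise ValueError(f"records reference species absent from metadata: {unknown}")

    band_dates = pd.to_datetime(records["band_date"])
    rec_dates = pd.to_datetime(records["rec_date"])
    if (rec_dates < band_dates).any():
        bad = records.loc[rec_dates < band_dates, "band_id"].tolist()
        raise ValueError(f"recovery precedes banding for records: {bad}")

    keep = np.ones(len(records), dtype=bool)
    rows = list(records.itertuples(index=False))
    for i, row in enumerate(rows):
        meta = meta_table[row.species]
        bd, rd = band_dates.iloc[i].date(), rec_dates.iloc[i].date()
        bp = GeoPoint(row.band_lat, row.band_lon)
        rp = GeoPoint(row.rec_lat, row.rec_lon)
        checks = (
            ("age", row.age_code in config.nestling_codes),
            ("maturity", _elapsed_years(bd, rd) >= config.maturity_years),
            ("season", in_breeding_season(bd, meta) and in_breeding_season(rd, meta)),
            ("range", in_breeding_bbox(bp, meta) and in_breeding_bbox(rp, meta)),
            ("condition", row.rec_condition in config.found_dead_codes),
            ("precision", config.precision_ok(row.precision_code)),
        )
        for name, ok in checks:
            if not ok:
                audit.removed[name] += 1
                keep[i] = False
                break

    retained = records.loc[keep].copy()
    audit.retained_count = len(retained)
    audit.check()
    return retained, audit


# ---------------------------------------------------------------------------
# estimation

def record_distances_km(
    records: pd.DataFrame, config: FilterConfig = FilterConfig()
) -> tuple[np.ndarray, int]:
    """Vincenty distance per record, with zero distances floored.

    Returns the distances and the count of floored (zero) distances.
    Identical banding/recovery coordinates reflect coordinate rounding, not
    a true zero displacement, so they are floored at half the 1' block
    resolution rather than producing -inf under the log.
    """
    dists = np.array(
        [
            vincenty_distance(
                GeoPoint(r.band_lat, r.band_lon), GeoPoint(r.rec_lat, r.rec_lon), WGS84
            )
            for r in records.itertuples(index=False)
        ]
    )
    floored = int((dists <= 0.0).sum())
    dists = np.maximum(dists, config.distance_floor_km)
    return dists, floored


def estimate_species_dispersal(
    records: pd.DataFrame, config: FilterConfig = FilterConfig()
) -> DispersalEstimate:
    """Geometric-mean dispersal distance for one species' retained records."""
    if len(records) == 0:
        raise ValueError("no records to estimate from")
    species = records["species"].iloc[0]
    if (records["species"] != species).any():
        raise ValueError("estimate_species_dispersal expects a single species")
    dists, _ = record_distances_km(records, config)
    logs = np.log(dists)
    geomean = float(np.exp(logs.mean()))
    log_se = float(logs.std(ddof=1) / np.sqrt(len(logs))) if len(logs) > 1 else np.nan
    years = [
        _elapsed_years(pd.Timestamp(r.band_date).date(), pd.Timestamp(r.rec_date).date())
        for r in records.itertuples(index=False)
    ]
    return DispersalEstimate(
        species=species,
        n=len(records),
        geomean_km=geomean,
        log_se=log_se,
        mean_recovery_years=float(np.mean(years)),
    )


def estimate_all_species(
    retained: pd.DataFrame, config: FilterConfig = FilterConfig()
) -> list[DispersalEstimate]:
    """One :class:`DispersalEstimate` per species, ordered by taxon key."""
    out = []
    for species in sorted(retained["species"].unique()):
        out.append(
            estimate_species_dispersal(
                retained.loc[retained["species"] == species], config
            )
        )
    return out


def retain_species(
    estimates: Iterable[DispersalEstimate], min_n: int = 5
) -> list[DispersalEstimate]:
    """Keep species with at least ``min_n`` recoveries, sorted by taxon key.

    Standard errors of the geometric mean blow up below five recoveries, so
    the default keeps species with n >= 5.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    return sorted(
        (e for e in estimates if e.n >= min_n), key=lambda e: e.species
    )


# ---------------------------------------------------------------------------
# I/O

def read_records_csv(path) -> pd.DataFrame:
    records = pd.read_csv(path, dtype={"band_id": str, "species": str})
    _require_columns(records)
    return records


def read_meta_csv(path) -> dict[str, SpeciesMeta]:
    df = pd.read_csv(path)
    metas = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        metas[d["species"]] = SpeciesMeta(
            species=d["species"],
            season_start_month=int(d["season_start_month"]),
            season_end_month=int(d["season_end_month"]),
            lat_min=float(d["lat_min"]),
            lat_max=float(d["lat_max"]),
            lon_min=float(d["lon_min"]),
            lon_max=float(d["lon_max"]),
            habitat=d.get("habitat", "woodlands"),
            diet=d.get("diet", "omnivore"),
            foraging=int(d.get("foraging", 1)),
            population_size=float(d.get("population_size", np.nan)),
            mass=float(d.get("mass", np.nan)),
            migration_distance=float(d.get("migration_distance", np.nan)),
            range_area=float(d.get("range_area", np.nan)),
            migratory=bool(d.get("migratory", False)),
        )
    return metas


def estimates_to_frame(estimates: Sequence[DispersalEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": e.species,
                "n": e.n,
                "geomean_km": e.geomean_km,
                "log_se": e.log_se,
                "mean_recovery_years": e.mean_recovery_years,
            }
            for e in estimates
        ]
    )
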