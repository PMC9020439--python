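"""Reading, validation and preprocessing of count-survey tables.

A survey table holds one record per (site, year) with a non-negative integer
count, plus per-site WGS84 coordinates.  Preprocessing covers the three steps
every downstream stage relies on: the coverage-retention filter (keep sites
counted in at least a minimum number of years), centering of the year
covariate, and projection of site coordinates to planar meters for gridding.

Zero counts are data and are kept; absent site-years are simply missing and
are never imputed — the unbalanced likelihood handles them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .projection import get_projection

logger = logging.getLogger(__name__)

#: Default column mapping for CSV input.
DEFAULT_DIALECT = {
    "site_id": "site_id",
    "year": "year",
    "count": "count",
    "lon": "lon",
    "lat": "lat",
}


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class IntegrityError(ValueError):
    """Record-level constraint violated (duplicates, negative counts...)."""


@dataclass
class SurveyTable:
    """Validated count-survey data.

    Attributes
    ----------
    records:
        DataFrame with columns ``site_id``, ``year``, ``count`` and, once
        :func:`center_years` has run, the centered year ``t``.
    sites:
        DataFrame with columns ``site_id``, ``lon``, ``lat`` and, once
        :func:`project_coordinates` has run, planar ``x``/``y`` in meters.
    center:
        Calendar year at which ``t`` is centered (None before centering).
    crs:
        Identifier of the projection behind ``x``/``y`` (None before
        projection).
    """

    records: pd.DataFrame
    sites: pd.DataFrame
    center: int | None = None
    crs: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- contracts -------------------------------------------------------
    def validate(self) -> None:
        for col in ("site_id", "year", "count"):
            if col not in self.records.columns:
                raise SchemaError(f"records missing column {col!r}")
        for col in ("site_id", "lon", "lat"):
            if col not in self.sites.columns:
                raise SchemaError(f"sites missing column {col!r}")
        counts = self.records["count"]
        if len(counts):
            arr = counts.to_numpy()
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.all(np.equal(np.mod(arr, 1), 0)):
                    raise IntegrityError("counts must be integers")
            if (arr < 0).any():
                raise IntegrityError("counts must be non-negative")
        dup = self.records.duplicated(subset=["site_id", "year"])
        if dup.any():
            keys = self.records.loc[dup, ["site_id", "year"]]
            listing = ", ".join(f"{s}/{y}" for s, y in keys.itertuples(index=False))
            raise IntegrityError(f"duplicate (site, year) records: {listing}")
        if self.sites["site_id"].duplicated().any():
            raise IntegrityError("duplicate site_id in site table")
        missing = set(self.records["site_id"]) - set(self.sites["site_id"])
        if missing:
            raise IntegrityError(f"records reference unknown sites: {sorted(map(str, missing))[:10]}")
        if self.center is not None and "t" in self.records.columns and len(self.records):
            if not (self.records["t"] == self.records["year"] - self.center).all():
                raise IntegrityError("t column inconsistent with center year")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def site_years(self) -> pd.Series:
        """Number of distinct surveyed years per site."""
        return self.records.groupby("site_id")["year"].nunique()


def read_counts(path, dialect: dict | None = None) -> SurveyTable:
    """Read a survey CSV into a validated :class:`SurveyTable`.

    ``dialect`` maps the canonical names (site_id, year, count, lon, lat)
    to the file's column names; omitted keys default to the canonical name.
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_DIALECT)
        if unknown:
            raise SchemaError(f"unknown dialect keys: {sorted(unknown)}")
        mapping.update(dialect)
    df = pd.read_csv(path)
    missing = [v for v in mapping.values() if v not in df.columns]
    if missing:
        raise SchemaError(f"input file {path} missing columns {missing}")
    df = df.rename(columns={v: k for k, v in mapping.items()})
    records = df[["site_id", "year", "count"]].copy()
    records["year"] = records["year"].astype(int)
    sites = (
        df[["site_id", "lon", "lat"]]
        .drop_duplicates(subset="site_id")
        .reset_index(drop=True)
    )
    # conflicting coordinates for one site are an integrity problem
    coord_card = df.groupby("site_id")[["lon", "lat"]].nunique()
    bad = coord_card[(coord_card > 1).any(axis=1)].index
    if len(bad):
        raise IntegrityError(f"sites with conflicting coordinates: {sorted(map(str, bad))[:10]}")
    table = SurveyTable(records=records, sites=sites)
    logger.info("read %d records / %d sites from %s", table.n_records, table.n_sites, path)
    return table


def write_counts(table: SurveyTable, path) -> None:
    """Write a survey table as CSV (site_id, year, count, lon, lat)."""
    merged = table.records.merge(table.sites[["site_id", "lon", "lat"]], on="site_id")
    merged[["site_id", "year", "count", "lon", "lat"]].to_csv(path, index=False)


def filter_by_coverage(table: SurveyTable, min_years: int = 7) -> SurveyTable:
    """Retain only sites surveyed in at least ``min_years`` distinct years.

    The default of 7 corresponds to a 60% coverage rule over an 11-year
    window.  Record order is preserved; the operation is idempotent.
    """
    if min_years < 1:
        raise ValueError("min_years must be >= 1")
    ny = table.site_years()
    keep = set(ny[ny >= min_years].index)
    records = table.records[table.records["site_id"].isin(keep)].reset_index(drop=True)
    sites = table.sites[table.sites["site_id"].isin(keep)].reset_index(drop=True)
    logger.info(
        "coverage filter (>=%d years): %d of %d sites retained",
        min_years, len(sites), table.n_sites,
    )
    return replace(table, records=records, sites=sites)


def filter_by_coverage_fraction(table: SurveyTable, min_fraction: float = 0.6) -> SurveyTable:
    """Fractional form of the retention rule.

    The absolute threshold is ``ceil(min_fraction * n_years)`` with
    ``n_years`` the number of distinct years present in the table.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    n_years = table.records["year"].nunique()
    return filter_by_coverage(table, int(np.ceil(min_fraction * n_years)))


def center_years(table: SurveyTable, center: int = 2007) -> SurveyTable:
    """Attach the centered year covariate t = year - center to every record.

    Centering at the middle of the study window decorrelates intercepts from
    slopes in the trend models.
    """
    records = table.records.copy()
    records["t"] = records["year"] - center
    return replace(table, records=records, center=center)


def project_coordinates(table: SurveyTable, crs: str = "laea-europe") -> SurveyTable:
    """Attach planar x/y (meters) to each site via the named projection."""
    proj = get_projection(crs)
    sites = table.sites.copy()
    if len(sites):
        x, y = proj.forward(sites["lon"].to_numpy(), sites["lat"].to_numpy())
        sites["x"], sites["y"] = x, y
    else:
        sites["x"] = pd.Series(dtype=float)
        sites["y"] = pd.Series(dtype=float)
    return replace(table, sites=sites, crs=crs if isinstance(crs, str) else "custom")
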