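"""Reading, validation, regional partitioning, and aggregation of catch
records into year x species biomass matrices.

The regional split is a fixed two-sector partition of the study box
(latitudes 0 to -60, split at the -20 meridian).  Boundary conventions
are half-open: the equator itself is outside the study area, and the
-20 meridian belongs to the eastern sector.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SINGLE_SPECIES = "single-species"
SPECIES_GROUP = "species-group"

#: Minimum acceptable share of total biomass retained after restricting
#: to single-species categories; below this a warning is emitted.
COVERAGE_WARN_THRESHOLD = 0.95


class SchemaError(ValueError):
    """A required column is missing from the input file."""


class ValidationError(ValueError):
    """One or more rows failed validation; offending rows are listed."""


class EmptyMatrixError(ValueError):
    """No records fall in the requested region."""


class Region(str, Enum):
    """Sector labels of the fixed spatial partition."""

    SWAO = "SWAO"  # study box, west of the split meridian
    SEAO = "SEAO"  # study box, on or east of the split meridian
    OUT = "OUT"  # outside the study box

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class CatchRecord:
    """One reported catch line.

    ``category_kind`` distinguishes true single-species categories from
    grouped categories (e.g. genus-level codes); grouped categories are
    retained on ingestion and removed later by
    :func:`filter_single_species`.
    """

    year: int
    species_code: str
    category_kind: str = SINGLE_SPECIES
    gear: str = ""
    flag: str = ""
    lat: float = float("nan")
    lon: float = float("nan")
    catch_tonnes: float = 0.0
    region: Region | None = None


#: Default mapping from record fields to input column names.
DEFAULT_SCHEMA: dict[str, str] = {
    "year": "year",
    "species_code": "species_code",
    "category_kind": "category_kind",
    "gear": "gear",
    "flag": "flag",
    "lat": "lat",
    "lon": "lon",
    "catch_tonnes": "catch_tonnes",
    "region": "region",
}

_REQUIRED_FIELDS = ("year", "species_code", "catch_tonnes")


def assign_region(lat: float, lon: float) -> Region:
    """Map a coordinate to its sector under the fixed partition.

    Half-open conventions: latitude in [-60, 0) is inside the study
    area (the equator is out); longitude < -20 is the western sector,
    longitude >= -20 (the split meridian included) is the eastern one.
    """
    if not (-90.0 <= lat <= 90.0):
        raise ValueError(f"latitude {lat} outside [-90, 90]")
    if not (-180.0 <= lon <= 180.0):
        raise ValueError(f"longitude {lon} outside [-180, 180]")
    if -60.0 <= lat < 0.0:
        return Region.SWAO if lon < -20.0 else Region.SEAO
    return Region.OUT


def read_catch_records(
    path,
    schema: Mapping[str, str] | None = None,
    study_window: tuple[int, int] | None = None,
    sep: str = ",",
) -> list[CatchRecord]:
    """Read a delimited catch file into validated records.

    Parameters
    ----------
    path
        CSV/TSV file with one catch line per row.
    schema
        Mapping from record fields to column names; unmapped optional
        fields fall back to :data:`DEFAULT_SCHEMA` names and are left
        at their defaults when the column is absent.  ``year``,
        ``species_code`` and ``catch_tonnes`` columns are mandatory.
    study_window
        Optional (first_year, last_year) inclusive bounds; rows outside
        are validation errors.

    Rows failing validation are reported with their file line numbers
    (header = line 1) in a single :class:`ValidationError`; nothing is
    silently dropped.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    frame = pd.read_csv(path, sep=sep)

    missing = [colmap[f] for f in _REQUIRED_FIELDS if colmap[f] not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")

    def col(field: str, default=None) -> pd.Series:
        name = colmap[field]
        if name in frame.columns:
            return frame[name]
        return pd.Series([default] * len(frame), index=frame.index)

    records: list[CatchRecord] = []
    problems: list[str] = []
    for i in range(len(frame)):
        line_no = i + 2  # header occupies line 1
        year = col("year").iloc[i]
        catch = col("catch_tonnes").iloc[i]
        lat = col("lat").iloc[i]
        lon = col("lon").iloc[i]
        region_label = col("region").iloc[i]
        errs = []
        if pd.isna(catch) or float(catch) < 0:
            errs.append(f"negative or missing catch {catch!r}")
        if study_window is not None and not (
            study_window[0] <= int(year) <= study_window[1]
        ):
            errs.append(f"year {year} outside study window {study_window}")
        have_coords = not (pd.isna(lat) or pd.isna(lon))
        region: Region | None = None
        if have_coords:
            if not (-90.0 <= float(lat) <= 90.0):
                errs.append(f"latitude {lat} out of range")
            elif not (-180.0 <= float(lon) <= 180.0):
                errs.append(f"longitude {lon} out of range")
            else:
                region = assign_region(float(lat), float(lon))
        elif region_label is not None and not pd.isna(region_label):
            # pre-gridded sources may carry a sector label instead of
            # coordinates; accept it as-is
            try:
                region = Region(str(region_label))
            except ValueError:
                errs.append(f"unknown region label {region_label!r}")
        else:
            errs.append("missing coordinates and no region label")
        if errs:
            problems.append(f"line {line_no}: " + "; ".join(errs))
            continue
        records.append(
            CatchRecord(
                year=int(year),
                species_code=str(col("species_code").iloc[i]),
                category_kind=str(col("category_kind", SINGLE_SPECIES).iloc[i]),
                gear=str(col("gear", "").iloc[i]),
                flag=str(col("flag", "").iloc[i]),
                lat=float(lat) if have_coords else float("nan"),
                lon=float(lon) if have_coords else float("nan"),
                catch_tonnes=float(catch),
                region=region,
            )
        )
    if problems:
        raise ValidationError(
            f"{len(problems)} invalid row(s) in {path}:\n" + "\n".join(problems)
        )
    return records


def filter_single_species(
    records: Sequence[CatchRecord], retained_species: Sequence[str]
) -> tuple[list[CatchRecord], float]:
    """Keep single-species records for the retained codes.

    Returns the kept records and the coverage fraction, i.e. the share
    of total biomass they represent.  A warning is emitted when the
    coverage drops below :data:`COVERAGE_WARN_THRESHOLD`.
    """
    if not records:
        raise ValueError("empty record list")
    if not retained_species:
        raise ValueError("retained_species must not be empty")
    keep = set(retained_species)
    total = sum(r.catch_tonnes for r in records)
    kept = [
        r
        for r in records
        if r.species_code in keep and r.category_kind == SINGLE_SPECIES
    ]
    retained = sum(r.catch_tonnes for r in kept)
    coverage = retained / total if total > 0 else 0.0
    if coverage < COVERAGE_WARN_THRESHOLD:
        warnings.warn(
            f"retained species cover only {coverage:.1%} of total biomass "
            f"(< {COVERAGE_WARN_THRESHOLD:.0%})",
            stacklevel=2,
        )
    return kept, coverage


def aggregate_matrix(
    records: Iterable[CatchRecord], region: Region
) -> pd.DataFrame:
    """Aggregate records of one region into a year x species matrix.

    Cell (y, s) is the summed tonnage over matching records; absent
    combinations are zero.  Species whose column is entirely zero are
    dropped (logged), since they carry no information downstream.
    """
    rows = [
        (r.year, r.species_code, r.catch_tonnes)
        for r in records
        if r.region == region
    ]
    if not rows:
        raise EmptyMatrixError(f"no records in region {region}")
    frame = pd.DataFrame(rows, columns=["year", "species", "tonnes"])
    matrix = (
        frame.pivot_table(
            index="year", columns="species", values="tonnes", aggfunc="sum"
        )
        .fillna(0.0)
        .sort_index()
    )
    zero_cols = matrix.columns[(matrix == 0).all(axis=0)]
    if len(zero_cols):
        logger.info("dropping all-zero species columns: %s", list(zero_cols))
        matrix = matrix.drop(columns=zero_cols)
    matrix.index.name = "year"
    matrix.columns.name = "species"
    return matrix


def validate_matrix(matrix: pd.DataFrame) -> None:
    """Check the invariants every downstream stage relies on."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("matrix contains negative cells")
    years = matrix.index.to_numpy()
    if len(years) > 1 and not (np.diff(years) > 0).all():
        raise ValueError("years must be strictly increasing")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate species columns")


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a matrix as CSV with a leading ``year`` column."""
    out = matrix.copy()
    out.index.name = "year"
    out.to_csv(path)


def read_matrix(path) -> pd.DataFrame:
    """Read a matrix written by :func:`write_matrix`."""
    matrix = pd.read_csv(path, index_col="year")
    matrix.columns.name = "species"
    validate_matrix(matrix)
    return matrix
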