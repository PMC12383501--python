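"""Thermal-affinity classification and catch-weighted temperature series.

The central statistic is the mean temperature of the catch (MTC): the
biomass-weighted mean of species' preferred temperatures within a year,

    MTC_y = sum_i T_i C_{i,y} / sum_i C_{i,y},

which rises when warm-affinity species come to dominate the catch.
Annual series are plain :class:`pandas.Series` indexed by calendar year;
missing years carry NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

WARM = "warm"
COLD = "cold"


@dataclass(frozen=True)
class ThermalAffinityTable:
    """Per-species preferred temperatures plus the warm/cold split.

    The threshold is always the arithmetic mean of the preferences in
    the table; a species is *warm* iff its preference is strictly above
    the threshold (ties count as cold).
    """

    preferences: pd.Series  # species_code -> preferred temperature (degC)
    threshold: float
    classes: pd.Series  # species_code -> "warm" | "cold"

    @property
    def warm_species(self) -> list[str]:
        return list(self.classes.index[self.classes == WARM])

    @property
    def cold_species(self) -> list[str]:
        return list(self.classes.index[self.classes == COLD])

    def to_csv(self, path) -> None:
        frame = pd.DataFrame(
            {"t_pref_c": self.preferences, "affinity": self.classes}
        )
        frame.index.name = "species_code"
        frame.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ThermalAffinityTable":
        frame = pd.read_csv(path, index_col="species_code")
        return classify_affinity(frame["t_pref_c"])


def classify_affinity(preferences: Mapping[str, float] | pd.Series) -> ThermalAffinityTable:
    """Build a :class:`ThermalAffinityTable` from raw preferences.

    The warm/cold threshold is the mean preference of the supplied
    table, so the canonical published threshold emerges when the
    published preference set is supplied, and any other table gets an
    internally consistent split.
    """
    prefs = pd.Series(preferences, dtype=float).rename("t_pref_c")
    if len(prefs) < 2:
        raise ValueError("need at least 2 species to classify affinities")
    if not np.isfinite(prefs.to_numpy()).all():
        raise ValueError("non-finite thermal preference encountered")
    if prefs.index.duplicated().any():
        raise ValueError("duplicate species codes in preference table")
    threshold = float(prefs.mean())
    classes = pd.Series(
        np.where(prefs.to_numpy() > threshold, WARM, COLD), index=prefs.index
    )
    return ThermalAffinityTable(
        preferences=prefs, threshold=threshold, classes=classes
    )


def classify_with_threshold(
    preferences: Mapping[str, float] | pd.Series, threshold: float
) -> ThermalAffinityTable:
    """Classify against an externally fixed threshold.

    Bypasses the table-mean rule; used when a published threshold must
    be applied to a partial species list.
    """
    prefs = pd.Series(preferences, dtype=float).rename("t_pref_c")
    if len(prefs) < 1:
        raise ValueError("empty preference table")
    classes = pd.Series(
        np.where(prefs.to_numpy() > threshold, WARM, COLD), index=prefs.index
    )
    return ThermalAffinityTable(
        preferences=prefs, threshold=float(threshold), classes=classes
    )


def _check_species(matrix: pd.DataFrame, table: ThermalAffinityTable) -> None:
    missing = matrix.columns.difference(table.preferences.index)
    if len(missing):
        raise KeyError(
            f"species without a thermal preference: {sorted(missing)}"
        )


def compute_mtc(matrix: pd.DataFrame, table: ThermalAffinityTable) -> pd.Series:
    """Annual mean temperature of the catch.

    Years with zero total catch are flagged missing (NaN), never zero.
    Every species in the matrix must have a preference.
    """
    _check_species(matrix, table)
    temps = table.preferences.reindex(matrix.columns).to_numpy(float)
    catch = matrix.to_numpy(float)
    if (catch < 0).any():
        raise ValueError("negative catch in matrix")
    totals = catch.sum(axis=1)
    with np.errstate(invalid="ignore"):
        values = np.where(totals > 0, catch @ temps / np.where(totals > 0, totals, 1.0), np.nan)
    return pd.Series(values, index=matrix.index, name="mtc")


def warm_fraction_series(
    matrix: pd.DataFrame,
    table: ThermalAffinityTable,
    by: str = "biomass",
) -> pd.Series:
    """Annual warm-affinity fraction of the catch.

    ``by="biomass"`` (default) is warm-class biomass over total biomass.
    ``by="count"`` is the fraction of species present (positive catch)
    that year that are warm-class; this secondary variant exists because
    "proportion of species" is ambiguous between the two readings.
    """
    _check_species(matrix, table)
    warm = matrix.columns.isin(table.warm_species)
    catch = matrix.to_numpy(float)
    if by == "biomass":
        totals = catch.sum(axis=1)
        num = catch[:, warm].sum(axis=1)
        values = np.where(totals > 0, num / np.where(totals > 0, totals, 1.0), np.nan)
    elif by == "count":
        present = catch > 0
        totals = present.sum(axis=1)
        num = present[:, warm].sum(axis=1)
        values = np.where(totals > 0, num / np.where(totals > 0, totals, 1), np.nan)
    else:
        raise ValueError(f"unknown mode {by!r}")
    return pd.Series(values, index=matrix.index, name=f"warm_fraction_{by}")


def warm_cold_ratio(matrix: pd.DataFrame, table: ThermalAffinityTable) -> float:
    """Warm:cold biomass ratio summed over the whole series."""
    _check_species(matrix, table)
    warm = matrix.columns.isin(table.warm_species)
    warm_total = float(matrix.loc[:, warm].to_numpy().sum())
    cold_total = float(matrix.loc[:, ~warm].to_numpy().sum())
    if cold_total == 0:
        return float("inf") if warm_total > 0 else float("nan")
    return warm_total / cold_total


def to_anomaly(series: pd.Series) -> pd.Series:
    """Center a series on its long-term mean (missing values ignored).

    Idempotent: the anomaly of an anomaly is itself.
    """
    values = series.to_numpy(float)
    n_obs = int(np.sum(~np.isnan(values)))
    if n_obs == 0:
        raise ValueError("cannot compute anomalies of an all-missing series")
    if n_obs < 2:
        warnings.warn("anomaly of a single observation is identically zero", stacklevel=2)
    out = series - np.nanmean(values)
    out.name = f"{series.name}_anomaly" if series.name else "anomaly"
    return out


def write_series(series: pd.Series, path, value_name: str = "value") -> None:
    frame = series.rename(value_name).to_frame()
    frame.index.name = "year"
    frame.to_csv(path)


def read_series(path, value_name: str = "value") -> pd.Series:
    frame = pd.read_csv(path, index_col="year")
    return frame[value_name]
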