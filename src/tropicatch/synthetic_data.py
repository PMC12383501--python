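"""Seeded generators for catch matrices, thermal-preference tables, and
environmental series with known planted structure.

Every pipeline stage can be exercised without external data: the
generator plants a linear shift of biomass share from cold- to
warm-affinity species (a controllable "tropicalization" signal), linear
warming in the environmental series, and log-normal multiplicative
noise on catches.  All randomness flows from one scenario seed expanded
into fixed per-component substreams, so adding a component never shifts
the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from tropicatch.thermal_mtc import (
    WARM,
    ThermalAffinityTable,
    classify_affinity,
)

# fixed substream keys: appending new components keeps old draws stable
_STREAM_THERMAL = 0
_STREAM_CATCH = 1
_STREAM_SST = 2
_STREAM_BCT = 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stream,))
    )


@dataclass(frozen=True)
class ScenarioParams:
    """Knobs of one synthetic scenario.

    ``share_trend`` is the per-species linear trend in log biomass
    share per year (scalar = same for all species); ``baseline_share``
    defaults to a geometric profile so a few taxa dominate, mirroring
    real catch compositions.  The year index is centered at the series
    midpoint inside the generator, which keeps intercepts interpretable
    and the design well conditioned.
    """

    n_years: int = 41
    n_species: int = 29
    warm_fraction: float = 16 / 29
    thermal_range: tuple[float, float] = (10.0, 29.0)
    baseline_share: Union[np.ndarray, None] = None
    share_trend: Union[np.ndarray, float] = 0.0
    total_catch_trend: float = 1.0
    base_total: float = 300_000.0
    noise_sd: float = 0.0
    sst0: float = 23.7
    sst_slope: float = 0.0
    sst_noise_sd: float = 0.0
    bct0: float = -22.0
    bct_slope: float = 0.0
    bct_noise_sd: float = 0.0
    start_year: int = 1978
    seed: int = 0

    def validate(self) -> None:
        if self.n_years < 5:
            raise ValueError("n_years must be >= 5")
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        for name in ("noise_sd", "sst_noise_sd", "bct_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.thermal_range
        if not lo < hi:
            raise ValueError("thermal_range must be (min, max) with min < max")
        if self.baseline_share is not None:
            shares = np.asarray(self.baseline_share, float)
            if len(shares) != self.n_species or (shares < 0).any():
                raise ValueError(
                    "baseline_share must hold n_species non-negative values"
                )
        n_warm = int(round(self.warm_fraction * self.n_species))
        if not 1 <= n_warm <= self.n_species - 1:
            raise ValueError(
                f"warm_fraction {self.warm_fraction} infeasible: a table's "
                "own mean always leaves at least one species on each side"
            )

    # -- derived helpers -------------------------------------------------
    @property
    def years(self) -> np.ndarray:
        return self.start_year + np.arange(self.n_years)

    @property
    def centered_t(self) -> np.ndarray:
        return np.arange(self.n_years) - (self.n_years - 1) / 2.0

    def species_codes(self) -> list[str]:
        return [f"SP{i + 1:02d}" for i in range(self.n_species)]

    def baseline(self) -> np.ndarray:
        if self.baseline_share is not None:
            shares = np.asarray(self.baseline_share, float)
        else:
            shares = 0.7 ** np.arange(self.n_species)
        return shares / shares.sum()

    def trends(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.share_trend, float), (self.n_species,)
        ).copy()


@dataclass(frozen=True)
class Scenario:
    """A fully generated input bundle."""

    params: ScenarioParams
    table: ThermalAffinityTable
    matrix: pd.DataFrame
    sst: pd.Series
    bct: pd.Series
    expected_mtc: pd.Series  # the noise-free MTC path implied by the shares


def generate_thermal_table(params: ScenarioParams) -> ThermalAffinityTable:
    """Draw species preferences with a requested warm fraction.

    Preferences are uniform in ``thermal_range``, redrawn (deterministic
    given the seed) until exactly ``round(warm_fraction * n_species)``
    of them lie strictly above the table's own mean.
    """
    params.validate()
    n_warm = int(round(params.warm_fraction * params.n_species))
    rng = _rng(params.seed, _STREAM_THERMAL)
    lo, hi = params.thermal_range
    for _ in range(100_000):
        prefs = rng.uniform(lo, hi, size=params.n_species)
        if int((prefs > prefs.mean()).sum()) == n_warm:
            return classify_affinity(
                pd.Series(prefs, index=params.species_codes())
            )
    raise ValueError(
        f"could not realize warm_fraction {params.warm_fraction} "
        f"within the sampling budget"
    )


def _share_paths(params: ScenarioParams) -> np.ndarray:
    """Noise-free per-year biomass shares, shape (n_years, n_species)."""
    t = params.centered_t[:, None]
    raw = params.baseline()[None, :] * np.exp(params.trends()[None, :] * t)
    return raw / raw.sum(axis=1, keepdims=True)


def expected_mtc_path(
    params: ScenarioParams, table: ThermalAffinityTable
) -> pd.Series:
    """Analytic noise-free MTC series implied by the share model."""
    temps = table.preferences.reindex(params.species_codes()).to_numpy(float)
    values = _share_paths(params) @ temps
    return pd.Series(values, index=params.years, name="expected_mtc")


def planted_mtc_slope(
    params: ScenarioParams, table: ThermalAffinityTable
) -> float:
    """OLS slope (degC/yr) of the noise-free MTC path on year."""
    path = expected_mtc_path(params, table)
    x = path.index.to_numpy(float)
    return float(np.polyfit(x, path.to_numpy(), 1)[0])


def generate_catch_matrix(
    params: ScenarioParams, table: ThermalAffinityTable
) -> pd.DataFrame:
    """Year x species biomass with log-normal multiplicative noise.

    cell(y, s) = total_y * share_s(y) * exp(eps),  eps ~ N(0, noise_sd^2),
    with share_s(y) proportional to baseline_s * exp(trend_s * t_y) and
    total_y following the multiplicative annual trend.
    """
    params.validate()
    if len(table.preferences) != params.n_species:
        raise ValueError("thermal table size does not match n_species")
    rng = _rng(params.seed, _STREAM_CATCH)
    shares = _share_paths(params)
    totals = params.base_total * params.total_catch_trend ** params.centered_t
    noise = np.exp(
        rng.normal(0.0, params.noise_sd, size=(params.n_years, params.n_species))
    )
    cells = totals[:, None] * shares * noise
    matrix = pd.DataFrame(
        cells, index=pd.Index(params.years, name="year"),
        columns=pd.Index(params.species_codes(), name="species"),
    )
    return matrix


def generate_within_warm_shift_matrix(
    params: ScenarioParams, table: ThermalAffinityTable
) -> pd.DataFrame:
    """Shift composition *within* the warm group only.

    The warm-group and cold-group total shares are held constant at
    their baseline values while the warm species rotate amongst
    themselves per ``share_trend``; a specificity control: the
    cold/warm biomass ratio carries no trend even though single-species
    series do.
    """
    params.validate()
    codes = params.species_codes()
    warm = table.classes.reindex(codes).to_numpy() == WARM
    base = params.baseline()
    t = params.centered_t[:, None]
    raw = base[None, :] * np.exp(params.trends()[None, :] * t)
    shares = np.empty((params.n_years, params.n_species))
    for mask in (warm, ~warm):
        block = raw[:, mask]
        block_share = block / block.sum(axis=1, keepdims=True)
        shares[:, mask] = block_share * base[mask].sum()
    rng = _rng(params.seed, _STREAM_CATCH)
    totals = params.base_total * params.total_catch_trend ** params.centered_t
    noise = np.exp(
        rng.normal(0.0, params.noise_sd, size=(params.n_years, params.n_species))
    )
    return pd.DataFrame(
        totals[:, None] * shares * noise,
        index=pd.Index(params.years, name="year"),
        columns=pd.Index(codes, name="species"),
    )


def generate_env_series(params: ScenarioParams) -> tuple[pd.Series, pd.Series]:
    """Annual temperature and current-transport series: linear + noise."""
    params.validate()
    t = params.centered_t
    years = pd.Index(params.years, name="year")
    sst = pd.Series(
        params.sst0
        + params.sst_slope * t
        + _rng(params.seed, _STREAM_SST).normal(0, params.sst_noise_sd, params.n_years),
        index=years,
        name="sst",
    )
    bct = pd.Series(
        params.bct0
        + params.bct_slope * t
        + _rng(params.seed, _STREAM_BCT).normal(0, params.bct_noise_sd, params.n_years),
        index=years,
        name="bct",
    )
    return sst, bct


def generate_scenario(
    params: ScenarioParams, table: ThermalAffinityTable | None = None
) -> Scenario:
    """Generate the full input bundle for one scenario."""
    params.validate()
    if table is None:
        table = generate_thermal_table(params)
    matrix = generate_catch_matrix(params, table)
    sst, bct = generate_env_series(params)
    return Scenario(
        params=params,
        table=table,
        matrix=matrix,
        sst=sst,
        bct=bct,
        expected_mtc=expected_mtc_path(params, table),
    )


def null_scenario(params: ScenarioParams) -> Scenario:
    """The same scenario with every planted trend removed.

    Used for type-I-error and permutation-uniformity checks: any
    detection on a null bundle is a false positive.
    """
    flat = replace(
        params,
        share_trend=0.0,
        total_catch_trend=1.0,
        sst_slope=0.0,
        bct_slope=0.0,
    )
    return generate_scenario(flat)


def tropicalization_preset(
    seed: int = 0,
    target_mtc_slope: float = 0.012,
    n_years: int = 41,
    noise_sd: float = 0.1,
    **overrides,
) -> tuple[ScenarioParams, ThermalAffinityTable]:
    """Scenario with a planted MTC slope of known magnitude.

    The warm-group log-share trend is calibrated so the OLS slope of
    the *noise-free* MTC path equals ``target_mtc_slope`` (degC/yr)
    exactly; noisy replicates then scatter around it.
    """
    params = ScenarioParams(
        n_years=n_years,
        noise_sd=noise_sd,
        total_catch_trend=overrides.pop("total_catch_trend", 1.016),
        sst_slope=0.008,
        sst_noise_sd=overrides.pop("sst_noise_sd", 0.15),
        bct_slope=0.366,
        bct_noise_sd=overrides.pop("bct_noise_sd", 3.0),
        seed=seed,
        **overrides,
    )
    table = generate_thermal_table(params)
    warm = (
        table.classes.reindex(params.species_codes()).to_numpy() == WARM
    ).astype(float)

    def slope_at(g: float) -> float:
        return planted_mtc_slope(replace(params, share_trend=g * warm), table)

    gain = brentq(lambda g: slope_at(g) - target_mtc_slope, 0.0, 2.0)
    params = replace(params, share_trend=gain * warm)
    return params, table
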