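"""Total beta diversity with year/species decomposition and permutation
inference, plus pairwise temporal beta-diversity indices decomposed
into biomass gains and losses.

The decomposition follows the total-variance view of beta diversity:
column-center the (transformed) community matrix, sum the squared
deviations (SStotal), divide by n - 1 (BDtotal), and attribute shares
of SStotal to years (YCBD) and species (SCBD).  Temporal indices use
the percentage-difference dissimilarity, whose numerator splits
exactly into a loss and a gain component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tropicatch.composition import METRIC_PERCENT_DIFF


@dataclass(frozen=True)
class BetaDivResult:
    """Total beta diversity and its year/species decomposition."""

    ss_total: float
    bd_total: float  # ss_total / (n - 1)
    scbd: pd.Series  # per-species share of ss_total (sums to 1)
    ycbd: pd.Series  # per-year share of ss_total (sums to 1)
    ycbd_p: pd.Series | None = None
    n_perm: int = 0
    seed: int | None = None


def beta_decompose(transformed: pd.DataFrame) -> BetaDivResult:
    """Decompose total variance into year and species contributions.

    For a constant matrix SStotal is zero and the contribution shares
    are undefined (returned as NaN).
    """
    if transformed.shape[0] < 2 or transformed.shape[1] < 2:
        raise ValueError("need at least 2 years and 2 species")
    Y = transformed.to_numpy(float)
    deviations = Y - Y.mean(axis=0)
    squares = deviations**2
    ss_total = float(squares.sum())
    n = Y.shape[0]
    bd_total = ss_total / (n - 1)
    # an (effectively) constant matrix has no beta diversity to share out;
    # the threshold is relative to the matrix magnitude to absorb float fuzz
    if ss_total <= 1e-12 * max(float((Y**2).sum()), np.finfo(float).tiny):
        nan_y = pd.Series(np.nan, index=transformed.index, name="ycbd")
        nan_s = pd.Series(np.nan, index=transformed.columns, name="scbd")
        return BetaDivResult(0.0, 0.0, scbd=nan_s, ycbd=nan_y)
    ycbd = pd.Series(squares.sum(axis=1) / ss_total, index=transformed.index, name="ycbd")
    scbd = pd.Series(squares.sum(axis=0) / ss_total, index=transformed.columns, name="scbd")
    return BetaDivResult(ss_total, bd_total, scbd=scbd, ycbd=ycbd)


def ycbd_permutation_test(
    transformed: pd.DataFrame, n_perm: int = 999, seed: int | None = None
) -> pd.Series:
    """Permutation p-values for the per-year contributions.

    Each permutation shuffles the values independently within every
    species column; p_y = (#{permuted ycbd_y >= observed} + 1) /
    (n_perm + 1), so the smallest attainable p is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = beta_decompose(transformed).ycbd.to_numpy()
    Y = transformed.to_numpy(float)
    n, p = Y.shape
    rng = np.random.default_rng(seed)
    count = np.zeros(n)
    # permute column-wise in manageable batches to bound memory
    batch = max(1, min(n_perm, int(2e7 / (n * p))))
    done = 0
    while done < n_perm:
        m = min(batch, n_perm - done)
        piles = np.broadcast_to(Y, (m, n, p)).copy()
        piles = rng.permuted(piles, axis=1)  # within-column shuffles
        centered = piles - piles.mean(axis=1, keepdims=True)
        squares = centered**2
        totals = squares.sum(axis=(1, 2))
        totals = np.where(totals > 0, totals, 1.0)
        perm_ycbd = squares.sum(axis=2) / totals[:, None]
        count += (perm_ycbd >= observed[None, :] - 1e-15).sum(axis=0)
        done += m
    p_values = (count + 1.0) / (n_perm + 1.0)
    return pd.Series(p_values, index=transformed.index, name="ycbd_p")


def beta_diversity_with_test(
    transformed: pd.DataFrame, n_perm: int = 999, seed: int | None = None
) -> BetaDivResult:
    """:func:`beta_decompose` plus the YCBD permutation test."""
    base = beta_decompose(transformed)
    p_values = ycbd_permutation_test(transformed, n_perm=n_perm, seed=seed)
    return BetaDivResult(
        ss_total=base.ss_total,
        bd_total=base.bd_total,
        scbd=base.scbd,
        ycbd=base.ycbd,
        ycbd_p=p_values,
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# temporal beta-diversity indices


@dataclass(frozen=True)
class TBIResult:
    """Pairwise year-to-year change decomposed into losses and gains.

    For the ordered pair (u, v), u earlier:
      A = common biomass, B = losses (u -> v), C = gains (u -> v),
      loss share = B/(2A+B+C), gain share = C/(2A+B+C),
      D = loss share + gain share  (the percentage difference),
      S = gain share - loss share  (signed: > 0 means gains dominate).

    Matrices are indexed [u, v]; D is symmetric, S antisymmetric.
    """

    common: pd.DataFrame  # A
    losses: pd.DataFrame  # B
    gains: pd.DataFrame  # C
    loss_share: pd.DataFrame
    gain_share: pd.DataFrame
    dissimilarity: pd.DataFrame  # D
    signed: pd.DataFrame  # S

    def to_long(self) -> pd.DataFrame:
        """Upper-triangle (u < v) pairs in long format."""
        years = self.common.index
        rows = []
        for i, u in enumerate(years):
            for j in range(i + 1, len(years)):
                v = years[j]
                rows.append(
                    {
                        "year_u": u,
                        "year_v": v,
                        "A": self.common.iloc[i, j],
                        "B": self.losses.iloc[i, j],
                        "C": self.gains.iloc[i, j],
                        "loss_share": self.loss_share.iloc[i, j],
                        "gain_share": self.gain_share.iloc[i, j],
                        "D": self.dissimilarity.iloc[i, j],
                        "S": self.signed.iloc[i, j],
                    }
                )
        return pd.DataFrame(rows)


def tbi_pairwise(matrix: pd.DataFrame) -> TBIResult:
    """Temporal beta-diversity components for every pair of years.

    Operates on raw (untransformed) biomass with the percentage
    difference index.
    """
    values = matrix.to_numpy(float)
    if (values < 0).any():
        raise ValueError("negative biomass")
    if len(values) < 2:
        raise ValueError("need at least 2 years")
    u = values[:, None, :]
    v = values[None, :, :]
    common = np.minimum(u, v).sum(axis=2)
    losses = np.clip(u - v, 0, None).sum(axis=2)
    gains = np.clip(v - u, 0, None).sum(axis=2)
    denom = 2 * common + losses + gains
    safe = np.where(denom > 0, denom, 1.0)
    loss_share = losses / safe
    gain_share = gains / safe

    def wrap(arr: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(arr, index=matrix.index, columns=matrix.index)

    return TBIResult(
        common=wrap(common),
        losses=wrap(losses),
        gains=wrap(gains),
        loss_share=wrap(loss_share),
        gain_share=wrap(gain_share),
        dissimilarity=wrap(loss_share + gain_share),
        signed=wrap(gain_share - loss_share),
    )


@dataclass(frozen=True)
class GainLossTest:
    """Paired comparison of gain vs loss shares across year pairs."""

    mean_difference: float  # mean(gain share - loss share)
    t_statistic: float | None
    p_value: float | None
    n_pairs: int
    direction: str  # "gains" | "losses" | "balanced"
    exact_equality: bool = False


def tbi_gain_loss_test(
    result: TBIResult, pairs: Sequence[tuple] | None = None
) -> GainLossTest:
    """Paired t-test of gain shares against loss shares.

    ``pairs`` selects (year_u, year_v) tuples, e.g. all pairs spanning
    two chronological groups; by default every u < v pair is used.
    With zero variance of the differences no t statistic exists and an
    exact-equality/constant-difference report is returned instead.
    """
    years = list(result.common.index)
    if pairs is None:
        pairs = [
            (years[i], years[j])
            for i in range(len(years))
            for j in range(i + 1, len(years))
        ]
    if len(pairs) < 2:
        raise ValueError("need at least 2 year pairs")
    gains = np.array([result.gain_share.loc[u, v] for u, v in pairs])
    losses = np.array([result.loss_share.loc[u, v] for u, v in pairs])
    diffs = gains - losses
    mean_diff = float(diffs.mean())
    direction = "gains" if mean_diff > 0 else ("losses" if mean_diff < 0 else "balanced")
    if np.ptp(diffs) == 0:
        return GainLossTest(
            mean_difference=mean_diff,
            t_statistic=None,
            p_value=None,
            n_pairs=len(pairs),
            direction=direction,
            exact_equality=True,
        )
    t_stat, p_value = stats.ttest_rel(gains, losses)
    return GainLossTest(
        mean_difference=mean_diff,
        t_statistic=float(t_stat),
        p_value=float(p_value),
        n_pairs=len(pairs),
        direction=direction,
    )


def check_tbi_consistency(result: TBIResult, dist: pd.DataFrame) -> bool:
    """Cross-module check: D equals the percentage-difference matrix."""
    if dist.attrs.get("metric") != METRIC_PERCENT_DIFF:
        raise ValueError("expected a percentage-difference distance matrix")
    return bool(
        np.allclose(result.dissimilarity.to_numpy(), dist.to_numpy(), atol=1e-12)
    )
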