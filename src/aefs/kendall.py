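"""Kendall coefficient of concordance W over per-class method recalls.

In the screening evaluation each activity class acts as a *judge* that
ranks the competing similarity methods (the *objects*) by the recall they
achieved on that class.  Kendall's W in [0, 1] measures how consistently
the classes agree on the method ordering:

    R_i = Σ_j r_ij          (total rank of method i over the m classes)
    S   = Σ_i (R_i − R̄)²    (sum of squared deviations of the totals)
    W   = 12 S / (m² (n³ − n))

with m judges and n objects.  Ranks within a judge are assigned ascending
with recall (higher recall ⇒ higher rank); ties receive average ranks.
W is invariant to a constant rank offset, so both 0-based and 1-based
conventions give the same W; mean ranks (R_i / m) are reported at the
chosen offset.  The associated significance is assessed with the Friedman
chi-square χ² = m(n−1)W on n−1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class RankMatrix:
    """m × n matrix of within-judge ranks (rows = judges, cols = objects)."""

    ranks: np.ndarray
    offset: int = 0
    objects: tuple[str, ...] | None = None

    def __post_init__(self):
        r = np.asarray(self.ranks, dtype=float)
        if r.ndim != 2 or r.shape[0] < 1 or r.shape[1] < 2:
            raise ValueError("rank matrix must be m×n with n >= 2")
        # a valid row re-ranks to itself (tie-averaged permutation check)
        for row in r:
            if not np.allclose(stats.rankdata(row) + (self.offset - 1), row):
                raise ValueError("each row must hold a (tie-averaged) permutation of ranks")
        object.__setattr__(self, "ranks", r)

    @property
    def m(self) -> int:
        return self.ranks.shape[0]

    @property
    def n(self) -> int:
        return self.ranks.shape[1]


@dataclass(frozen=True)
class KendallResult:
    rank_totals: np.ndarray     # R_i per object
    mean_total: float           # R̄
    s: float                    # Σ (R_i − R̄)²
    w: float                    # coefficient of concordance
    mean_ranks: np.ndarray      # R_i / m
    chi_square: float
    df: int
    p_value: float
    m: int
    n: int
    objects: tuple[str, ...] | None = None


def rank_within_judges(recalls, offset: int = 0, objects=None) -> RankMatrix:
    """Rank objects within each judge row of a classes × methods recall matrix.

    Higher recall receives a higher rank; ranks start at *offset* (0 or 1)
    and ties get average ranks, e.g. row (5, 7, 7, 9) at offset 0 ranks as
    (0, 1.5, 1.5, 3).
    """
    R = np.asarray(recalls, dtype=float)
    if R.ndim != 2 or R.shape[0] < 1 or R.shape[1] < 2:
        raise ValueError("need a 2-D recall matrix with at least 2 methods")
    if np.any(np.isnan(R)):
        raise ValueError("non-numeric recall cell")
    # rankdata is 1-based ascending; shift to the requested offset
    ranks = np.vstack([stats.rankdata(row) for row in R]) + (offset - 1)
    if objects is not None:
        objects = tuple(objects)
    return RankMatrix(ranks=ranks, offset=offset, objects=objects)


def kendall_w(ranks: RankMatrix, tie_correction: bool = False) -> KendallResult:
    """Compute Kendall's W with rank totals, mean ranks and significance.

    With ``tie_correction`` the denominator is reduced by ``m Σ T_j`` where
    ``T_j = Σ (t³ − t)`` over tied groups of judge j; the default follows
    the uncorrected definition above.
    """
    m, n = ranks.m, ranks.n
    if n < 2:
        raise ValueError("need at least 2 objects")
    # W is offset-invariant; totals are reported at the matrix's own offset
    totals = ranks.ranks.sum(axis=0)
    mean_total = float(totals.mean())
    s = float(((totals - mean_total) ** 2).sum())
    denom = m * m * (n ** 3 - n)
    if tie_correction:
        t_sum = 0.0
        for row in ranks.ranks:
            _, counts = np.unique(row, return_counts=True)
            t_sum += float((counts ** 3 - counts).sum())
        denom -= m * t_sum
    if denom <= 0:
        raise ValueError("degenerate rank matrix: all objects tied everywhere")
    w = 12.0 * s / denom
    chi2 = m * (n - 1) * w
    df = n - 1
    p = float(stats.chi2.sf(chi2, df))
    return KendallResult(
        rank_totals=totals,
        mean_total=mean_total,
        s=s,
        w=float(w),
        mean_ranks=totals / m,
        chi_square=float(chi2),
        df=df,
        p_value=p,
        m=m,
        n=n,
        objects=ranks.objects,
    )


def friedman_chi_square(result: KendallResult) -> tuple[float, int, float]:
    """Friedman statistic χ² = m(n−1)W, its df = n−1 and upper-tail p."""
    return result.chi_square, result.df, result.p_value


def concordance_from_recalls(recalls, offset: int = 0, objects=None,
                             tie_correction: bool = False) -> KendallResult:
    """Convenience: :func:`rank_within_judges` then :func:`kendall_w`."""
    return kendall_w(rank_within_judges(recalls, offset=offset, objects=objects),
                     tie_correction=tie_correction)
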