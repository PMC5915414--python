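"""Abundance-based beta diversity between protected areas.

Pairwise dissimilarity between the species occurrence-probability vectors
of two PAs, using the Bray-Curtis partition of Baselga (2013): with

    A = sum_s min(x_s, y_s)     (shared mass)
    B = sum_s (x_s - min)       (mass lost from x)
    C = sum_s (y_s - min)       (mass gained by y)

the total Bray-Curtis dissimilarity (B+C)/(2A+B+C) splits additively into
a *balanced* component min(B,C)/(A+min(B,C)) — compensated gains and
losses, the abundance analogue of species turnover — and a *gradient*
component (the remainder) — a monotone surplus of one site over the
other, the abundance analogue of nestedness.

On binary (presence/absence) vectors the total reduces to the Sorensen
dissimilarity and the balanced component to the Simpson dissimilarity.

Probabilities enter raw: they are not rescaled by conservation weights and
not converted to pseudo-abundances.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, UndefinedDissimilarityError, ValidationError
from .occurrence_probability import OccurrenceProbabilityMatrix

__all__ = [
    "PairwiseDissimilarity",
    "bray_curtis_partition",
    "pairwise_components",
    "pairwise_table",
    "dissimilarity_summary",
]


@dataclass(frozen=True)
class PairwiseDissimilarity:
    total: float
    balanced: float
    gradient: float
    shared_mass: float  # A
    loss_mass: float  # B
    gain_mass: float  # C


def bray_curtis_partition(
    x: Sequence[float], y: Sequence[float]
) -> PairwiseDissimilarity:
    """Bray-Curtis dissimilarity between two sites, partitioned into its
    balanced (turnover-like) and gradient (nestedness-like) components.

    Raises :class:`UndefinedDissimilarityError` when both vectors are
    all-zero (no species mass at either site).
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise DomainError("vectors must be one-dimensional and equal length")
    if np.any(xv < 0) or np.any(yv < 0):
        raise DomainError("occurrence-probability vectors must be non-negative")
    m = np.minimum(xv, yv)
    a = float(m.sum())
    b = float((xv - m).sum())
    c = float((yv - m).sum())
    if a == 0.0 and b == 0.0 and c == 0.0:
        raise UndefinedDissimilarityError(
            "dissimilarity undefined for two empty assemblages"
        )
    total = (b + c) / (2 * a + b + c)
    mn = min(b, c)
    balanced = mn / (a + mn) if (a + mn) > 0 else 0.0
    return PairwiseDissimilarity(
        total=total,
        balanced=balanced,
        gradient=total - balanced,
        shared_mass=a,
        loss_mass=b,
        gain_mass=c,
    )


def pairwise_components(
    M: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense pairwise (total, balanced, gradient) matrices for site rows.

    Rows with zero total mass produce NaN against every partner; the
    diagonal is NaN. Vectorised: for a few hundred PAs the full n^2 x S
    minimum tensor fits comfortably in memory.
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    sums = M.sum(axis=1)
    A = np.minimum(M[:, None, :], M[None, :, :]).sum(axis=2)
    denom_tot = sums[:, None] + sums[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        total = (denom_tot - 2 * A) / denom_tot
    B = sums[:, None] - A
    C = sums[None, :] - A
    mn = np.minimum(B, C)
    denom_bal = A + mn
    with np.errstate(divide="ignore", invalid="ignore"):
        balanced = np.where(denom_bal > 0, mn / np.where(denom_bal > 0, denom_bal, 1.0), 0.0)
    gradient = total - balanced
    empty = sums == 0
    for comp in (total, balanced, gradient):
        comp[empty, :] = np.nan
        comp[:, empty] = np.nan
        np.fill_diagonal(comp, np.nan)
    return total, balanced, gradient


def pairwise_table(P: OccurrenceProbabilityMatrix) -> pd.DataFrame:
    """Long-format table of all PA pairs (i < j) and their components."""
    total, balanced, gradient = pairwise_components(P.values.to_numpy())
    ids = P.pa_ids
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rows.append(
                (ids[i], ids[j], total[i, j], balanced[i, j], gradient[i, j])
            )
    return pd.DataFrame(
        rows, columns=["pa_i", "pa_j", "total", "balanced", "gradient"]
    )


def dissimilarity_summary(P: OccurrenceProbabilityMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-PA mean of pairwise dissimilarities against all other PAs,
    plus the standard deviation of the pairwise totals.

    All-zero PA rows are excluded from pairing and reported as NaN.
    Requires at least two PAs with non-zero species mass.
    """
    values = P.values if isinstance(P, OccurrenceProbabilityMatrix) else P
    M = values.to_numpy(dtype=float)
    usable = M.sum(axis=1) > 0
    if usable.sum() < 2:
        raise ValidationError(
            "dissimilarity summary needs >= 2 PAs with non-zero rows"
        )
    total, balanced, gradient = pairwise_components(M)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        out = pd.DataFrame(
            {
                "mean_total": np.nanmean(total, axis=1),
                "mean_balanced": np.nanmean(balanced, axis=1),
                "mean_gradient": np.nanmean(gradient, axis=1),
                "sd_total": np.nanstd(total, axis=1),  # population SD over partners
            },
            index=values.index,
        ).rename_axis("pa_id")
    out.loc[~usable, :] = np.nan
    return out
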