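"""Per-PA conservation-value metrics.

* ``Richness_RS`` — expected number of reported species in a PA, the sum of
  the species' occurrence probabilities.
* Conservation weight ``w = 1/frequency`` — inverse of the number of grid
  cells a species occupies across the whole land grid (a rarity score).
* Rarity-weighted richness — sum of p * w; average rarity — their ratio.
* Species-area relationship (SAR) fitting with AIC selection among the
  Arrhenius power model S = b*A^c, Gleason's semi-log model
  S = y + z*ln(A), and a zero-intercept linear null S = m*A; the
  area-controlled surplus (%Surplus) is the SAR residual expressed as a
  percentage of the fitted richness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core_data_io import SpeciesOccurrence
from .errors import DomainError, FittingError, JoinError
from .occurrence_probability import OccurrenceProbabilityMatrix

__all__ = [
    "ConservationWeights",
    "SARFit",
    "SARModelSelection",
    "conservation_weight",
    "species_frequencies",
    "richness_rs",
    "rarity_weighted_richness",
    "rarity_mean",
    "fit_sar",
    "sar_surplus",
    "metric_table",
]

SAR_FAMILIES = ("arrhenius_power", "gleason_exponential", "linear_null_zero_intercept")

# number of fitted regression parameters per family (error variance adds 1 in AIC)
_N_PARAMS = {
    "arrhenius_power": 2,
    "gleason_exponential": 2,
    "linear_null_zero_intercept": 1,
}

_AIC_TIE = 1e-9
_SSE_FLOOR = 1e-300  # keeps AIC finite for exact-interpolation fits


# ---------------------------------------------------------------------------
# rarity weights
# ---------------------------------------------------------------------------


def conservation_weight(frequency: int) -> float:
    """w = 1/frequency for a species occupying ``frequency`` land cells."""
    if not float(frequency).is_integer() or frequency < 1:
        raise DomainError("frequency must be an integer >= 1")
    return 1.0 / int(frequency)


def species_frequencies(occurrences: Sequence[SpeciesOccurrence]) -> pd.Series:
    """Occupied-cell count per species over the full land grid."""
    return pd.Series(
        {occ.species_id: occ.frequency for occ in occurrences},
        dtype=int,
        name="frequency",
    )


@dataclass
class ConservationWeights:
    """Per-species rarity weights, computed once over the whole land grid.

    Never recompute these on a PA subset or a biased/cross-validation
    subset: the weight is defined against the full study region.
    """

    table: pd.DataFrame  # columns: frequency (int), w (float); index species_id

    @classmethod
    def from_occurrences(
        cls, occurrences: Sequence[SpeciesOccurrence]
    ) -> "ConservationWeights":
        freq = species_frequencies(occurrences)
        w = pd.Series(
            [conservation_weight(f) for f in freq], index=freq.index, name="w"
        )
        return cls(table=pd.DataFrame({"frequency": freq, "w": w}))

    @property
    def w(self) -> pd.Series:
        return self.table["w"]

    @property
    def frequency(self) -> pd.Series:
        return self.table["frequency"]

    def aligned_to(self, species_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in species_ids if s not in self.table.index]
        if missing:
            raise JoinError(f"no conservation weight for species {missing[:5]}")
        return self.table["w"].loc[list(species_ids)].to_numpy()

    def to_csv(self, path) -> None:
        self.table.rename_axis("species_id").to_csv(path)


# ---------------------------------------------------------------------------
# richness metrics
# ---------------------------------------------------------------------------


def _validate_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < -1e-12 or np.nanmax(p) > 1 + 1e-12):
        raise DomainError("probabilities must lie in [0, 1]")
    return p


def richness_rs(p_row: Sequence[float]) -> float:
    """Expected reported-species count: sum of occurrence probabilities."""
    return float(_validate_probs(p_row).sum())


def rarity_weighted_richness(
    p_row: Sequence[float], weights: Sequence[float]
) -> float:
    """Sum of p_i * w_i over the (aligned) species pool."""
    p = _validate_probs(p_row)
    w = np.asarray(weights, dtype=float)
    if p.shape != w.shape:
        raise JoinError("probability and weight vectors are misaligned")
    return float((p * w).sum())


def rarity_mean(rw: float, rr: float) -> float:
    """Average rarity of the species present: rw/rr, 0 for an empty PA."""
    if rr < 0:
        raise DomainError("richness must be >= 0")
    if rr == 0:
        return 0.0
    return rw / rr


# ---------------------------------------------------------------------------
# species-area relationship
# ---------------------------------------------------------------------------


@dataclass
class SARFit:
    family: str
    params: dict[str, float]
    sse: float
    aic: float
    fitted: np.ndarray
    residuals: np.ndarray

    def predict(self, areas: Sequence[float]) -> np.ndarray:
        A = np.asarray(areas, dtype=float)
        if self.family == "arrhenius_power":
            return self.params["b"] * A ** self.params["c"]
        if self.family == "gleason_exponential":
            return self.params["y"] + self.params["z"] * np.log(A)
        return self.params["slope"] * A


@dataclass
class SARModelSelection:
    fits: dict[str, SARFit]
    selected: str

    @property
    def best(self) -> SARFit:
        return self.fits[self.selected]


def _aic(sse: float, n: int, family: str) -> float:
    k = _N_PARAMS[family] + 1  # + error variance
    return n * np.log(max(sse, _SSE_FLOOR) / n) + 2 * k


def fit_sar(
    areas: Sequence[float],
    richness: Sequence[float],
    aicc: bool = False,
) -> SARModelSelection:
    """Least-squares fits of the three SAR candidates with AIC selection.

    All models minimise untransformed SSE on the richness scale. The
    Arrhenius fit is initialised from a log-log ordinary regression. AIC
    ties (delta < 1e-9) break toward the model with fewer parameters.
    ``aicc`` switches on the small-sample correction (off by default).
    """
    A = np.asarray(areas, dtype=float)
    S = np.asarray(richness, dtype=float)
    n = A.size
    if n < 3:
        raise FittingError(f"need >= 3 PAs to fit a SAR, got {n}")
    if S.size != n:
        raise FittingError("areas and richness have different lengths")
    if np.any(A <= 0):
        raise FittingError("PA areas must be positive")
    if np.ptp(A) == 0:
        raise FittingError("constant areas: area carries no information")

    fits: dict[str, SARFit] = {}

    # Arrhenius power: S = b * A^c, b > 0
    mask = S > 0
    if mask.sum() >= 2:
        coef = np.polyfit(np.log(A[mask]), np.log(S[mask]), 1)
        p0 = (float(np.exp(coef[1])), float(coef[0]))
    else:
        p0 = (1.0, 0.25)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda a, b, c: b * a**c,
                A,
                S,
                p0=p0,
                bounds=([1e-12, -10.0], [np.inf, 10.0]),
                maxfev=10000,
            )
    except (RuntimeError, ValueError) as exc:
        raise FittingError(f"Arrhenius fit failed to converge: {exc}") from exc
    fitted = popt[0] * A ** popt[1]
    sse = float(((S - fitted) ** 2).sum())
    fits["arrhenius_power"] = SARFit(
        "arrhenius_power",
        {"b": float(popt[0]), "c": float(popt[1])},
        sse,
        _aic(sse, n, "arrhenius_power"),
        fitted,
        S - fitted,
    )

    # Gleason semi-log: S = y + z * ln(A), closed-form OLS
    z, y = np.polyfit(np.log(A), S, 1)
    fitted = y + z * np.log(A)
    sse = float(((S - fitted) ** 2).sum())
    fits["gleason_exponential"] = SARFit(
        "gleason_exponential",
        {"y": float(y), "z": float(z)},
        sse,
        _aic(sse, n, "gleason_exponential"),
        fitted,
        S - fitted,
    )

    # zero-intercept linear null: S = m * A
    slope = float((A * S).sum() / (A * A).sum())
    fitted = slope * A
    sse = float(((S - fitted) ** 2).sum())
    fits["linear_null_zero_intercept"] = SARFit(
        "linear_null_zero_intercept",
        {"slope": slope},
        sse,
        _aic(sse, n, "linear_null_zero_intercept"),
        fitted,
        S - fitted,
    )

    if aicc:
        for fit in fits.values():
            k = _N_PARAMS[fit.family] + 1
            if n - k - 1 > 0:
                fit.aic += 2 * k * (k + 1) / (n - k - 1)

    for fit in fits.values():
        if not np.all(np.isfinite(fit.fitted)):
            raise FittingError(f"{fit.family}: non-finite fitted values")

    # minimum AIC; near-ties resolved toward the simpler family
    best = min(
        fits.values(), key=lambda f: (round(f.aic / _AIC_TIE), _N_PARAMS[f.family])
    )
    return SARModelSelection(fits=fits, selected=best.family)


def sar_surplus(observed, fitted):
    """SAR residual as a percentage of the fitted richness.

    100 * (observed - fitted) / fitted; e.g. observed 70 against fitted 50
    is +40%, observed 35 against fitted 50 is -30%.
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if np.any(fit <= 0):
        raise DomainError("fitted richness must be positive")
    out = 100.0 * (obs - fit) / fit
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# combined metric table
# ---------------------------------------------------------------------------


def metric_table(
    P: OccurrenceProbabilityMatrix,
    weights: ConservationWeights,
    areas: Mapping[str, float] | pd.Series,
    include_dissimilarity: bool = True,
) -> tuple[pd.DataFrame, SARModelSelection]:
    """Per-PA table of all conservation-value metrics.

    The SAR is (re)fitted on exactly the PA set present in ``P``, so a
    subset analysis (NP-only, MAB-only, single taxon) gets its own fit and
    its own %Surplus values.
    """
    from .beta_diversity import dissimilarity_summary  # local: avoid cycle

    values = P.values
    w = weights.aligned_to(values.columns)
    rr = values.to_numpy().sum(axis=1)
    rw = values.to_numpy() @ w
    rm = np.where(rr > 0, np.divide(rw, rr, out=np.zeros_like(rw), where=rr > 0), 0.0)
    area_vec = pd.Series(areas).loc[values.index].to_numpy(dtype=float)
    sel = fit_sar(area_vec, rr)
    surplus = sar_surplus(rr, sel.best.fitted)
    out = pd.DataFrame(
        {
            "richness_rs": rr,
            "richness_sar_pct_surplus": surplus,
            "richness_rarity_weighted": rw,
            "rarity_mean": rm,
        },
        index=values.index,
    ).rename_axis("pa_id")
    if include_dissimilarity and len(values) >= 2:
        summ = dissimilarity_summary(P)
        out["dissimilarity_total"] = summ["mean_total"]
        out["dissimilarity_balanced"] = summ["mean_balanced"]
        out["dissimilarity_gradient"] = summ["mean_gradient"]
        out["dissimilarity_sd"] = summ["sd_total"]
    return out, sel
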