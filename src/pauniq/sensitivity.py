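"""Sensitivity machinery: null models, rank tests, cross-validation and
spatially corrected correlations.

The null model destroys the spatial placement of every species while
conserving its occupied-cell count (hence its conservation weight): each
species is redistributed uniformly at random, without replacement, over
the land cells. Per-nation significance is assessed two ways, following
the study design this package implements:

* a paired two-sided Wilcoxon signed-rank test of each nation's observed
  per-PA metric values against their null-model expectations, and
* an unpaired two-sided Wilcoxon rank-sum (Mann-Whitney) test of the
  nation's observed values against the rest of the study region.

Leave-nations-out cross-validation drops a fixed number of nations per
run (their PAs and their occurrence records), recomputes the SAR surplus
(with a fresh fit) and the dissimilarity summaries on the retained set —
conservation weights stay fixed at their full-region values — and reports
the per-PA standard deviation across runs as an uncertainty measure.

Correlations between per-PA metrics use Pearson's r with a modified
t-test whose effective sample size accounts for spatial autocorrelation
(Clifford-Richardson/Dutilleul-type correction from distance-class Moran
correlograms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .beta_diversity import pairwise_components
from .core_data_io import AnalysisDataset, SpeciesOccurrence
from .diversity_metrics import ConservationWeights, fit_sar, sar_surplus
from .errors import DomainError, FittingError, ValidationError
from .occurrence_probability import (
    OccurrenceProbabilityMatrix,
    _log_complement,
    _probability_from_occupancy,
    build_matrix,
)

__all__ = [
    "NullModelEnsemble",
    "SensitivityReport",
    "CrossValReport",
    "SpatialCorrelationResult",
    "randomize_occurrences",
    "signed_rank_test",
    "rank_sum_test",
    "run_null_model_analysis",
    "cross_validate",
    "spatial_correlation",
]

NULL_METRICS = (
    "richness_rs",
    "richness_rarity_weighted",
    "rarity_mean",
    "sar_surplus",
    "dissimilarity_total",
    "dissimilarity_balanced",
    "dissimilarity_gradient",
)

CROSSVAL_METRICS = (
    "sar_surplus",
    "dissimilarity_total",
    "dissimilarity_balanced",
    "dissimilarity_gradient",
)

_EXACT_MAX_N = 25


# ---------------------------------------------------------------------------
# randomization
# ---------------------------------------------------------------------------


def randomize_occurrences(
    occurrences: Sequence[SpeciesOccurrence],
    land_cells: Sequence[str],
    rng: np.random.Generator,
) -> list[SpeciesOccurrence]:
    """Redistribute each species over ``land_cells`` uniformly at random,
    without replacement, keeping its occupied-cell count (frequency).

    Species are randomized independently of one another.
    """
    cells = np.asarray(list(land_cells), dtype=object)
    n = cells.size
    out = []
    for occ in occurrences:
        k = occ.frequency
        if k > n:
            raise DomainError(
                f"species {occ.species_id!r}: frequency {k} exceeds "
                f"{n} land cells"
            )
        chosen = rng.choice(n, size=k, replace=False)
        out.append(
            SpeciesOccurrence(
                species_id=occ.species_id,
                taxon_group=occ.taxon_group,
                occupied_cells=frozenset(cells[chosen]),
            )
        )
    return out


def _random_occupancy(
    rng: np.random.Generator, n_cells: int, freqs: np.ndarray
) -> np.ndarray:
    """(n_species x n_cells) boolean occupancy with exact row sums ``freqs``.

    Uniform subsets without replacement via per-row order statistics of a
    single uniform matrix.
    """
    R = rng.random((freqs.size, n_cells))
    kth = np.sort(R, axis=1)[np.arange(freqs.size), freqs - 1]
    return R <= kth[:, None]


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


def _clean_pairs(observed, expected):
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise DomainError("observed and expected vectors are misaligned")
    keep = np.isfinite(obs) & np.isfinite(exp)
    return obs[keep] - exp[keep]


def signed_rank_test(
    observed: Sequence[float],
    expected: Sequence[float],
    min_n: int = 5,
) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value, or NaN if untestable.

    Zero differences are discarded (Wilcoxon's treatment); with fewer than
    ``min_n`` non-zero differences left the nation is reported untested
    (NaN), never as p = 1. Small tie-free samples (n <= 25) use the exact
    null distribution, larger or tied samples the normal approximation
    with continuity correction.
    """
    d = _clean_pairs(observed, expected)
    d = d[d != 0.0]
    if d.size < min_n:
        return float("nan")
    exact = d.size <= _EXACT_MAX_N and np.unique(np.abs(d)).size == d.size
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        correction=not exact,
        alternative="two-sided",
        method="exact" if exact else "approx",
    )
    return float(res.pvalue)


def rank_sum_test(
    nation_values: Sequence[float],
    rest_values: Sequence[float],
    min_n: int = 5,
) -> float:
    """Two-sided unpaired Wilcoxon rank-sum (Mann-Whitney) p-value.

    NaN when the nation sample has fewer than ``min_n`` usable values;
    raises on an empty comparison sample. Exact when both samples are
    small and tie-free, otherwise normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(nation_values, dtype=float)
    y = np.asarray(rest_values, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if y.size == 0 or x.size == 0:
        raise ValidationError("rank-sum test needs two non-empty samples")
    if x.size < min_n:
        return float("nan")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0  # all values identical: indistinguishable samples
    no_ties = np.unique(pooled).size == pooled.size
    exact = no_ties and max(x.size, y.size) <= _EXACT_MAX_N
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# null-model analysis
# ---------------------------------------------------------------------------


@dataclass
class NullModelEnsemble:
    """Per-simulation per-PA metric values under the frequency-preserving
    null model."""

    values: dict[str, np.ndarray]  # metric -> (n_sims, n_pa)
    pa_ids: list[str]
    n_sims: int
    rng_seed: int | None


@dataclass
class SensitivityReport:
    table: pd.DataFrame  # one row per nation x metric
    eu_summary: pd.DataFrame  # one row per metric (observed + null pooled)
    ensemble: NullModelEnsemble
    observed: pd.DataFrame  # per-PA observed metric values
    alpha: float


def _metrics_from_probability(
    P: np.ndarray,
    w: np.ndarray,
    areas: np.ndarray,
    metrics: Sequence[str],
) -> dict[str, np.ndarray]:
    """Per-PA metric vectors from a dense (n_pa x n_species) probability
    matrix. Richness is always computed; the rest on demand."""
    out: dict[str, np.ndarray] = {}
    rr = P.sum(axis=1)
    if "richness_rs" in metrics:
        out["richness_rs"] = rr
    if "richness_rarity_weighted" in metrics or "rarity_mean" in metrics:
        rw = P @ w
        if "richness_rarity_weighted" in metrics:
            out["richness_rarity_weighted"] = rw
        if "rarity_mean" in metrics:
            out["rarity_mean"] = np.where(
                rr > 0, np.divide(rw, rr, out=np.zeros_like(rw), where=rr > 0), 0.0
            )
    if "sar_surplus" in metrics:
        try:
            sel = fit_sar(areas, rr)
            out["sar_surplus"] = sar_surplus(rr, sel.best.fitted)
        except (FittingError, DomainError):
            out["sar_surplus"] = np.full(rr.shape, np.nan)
    if any(m.startswith("dissimilarity") for m in metrics):
        total, balanced, gradient = pairwise_components(P)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if "dissimilarity_total" in metrics:
                out["dissimilarity_total"] = np.nanmean(total, axis=1)
            if "dissimilarity_balanced" in metrics:
                out["dissimilarity_balanced"] = np.nanmean(balanced, axis=1)
            if "dissimilarity_gradient" in metrics:
                out["dissimilarity_gradient"] = np.nanmean(gradient, axis=1)
    return out


def _iqr(values: np.ndarray) -> tuple[float, float]:
    v = values[np.isfinite(values)]
    if v.size == 0:
        return float("nan"), float("nan")
    return tuple(np.percentile(v, [25, 75]))


def run_null_model_analysis(
    dataset: AnalysisDataset,
    metrics: Sequence[str] = NULL_METRICS,
    n_sims: int = 1000,
    seed: int | None = None,
    min_n: int = 5,
    alpha: float = 0.05,
    weights: ConservationWeights | None = None,
    pairing: str = "mean",
    per_sim_medians: bool = False,
) -> SensitivityReport:
    """Null-model randomization plus per-nation significance tests.

    For every nation with at least ``min_n`` single-nation PAs and every
    metric, tests (i) observed vs null-expected per-PA values (paired
    signed-rank; each PA paired with the mean — or median, with
    ``pairing='median'`` — of its simulated values) and (ii) observed
    nation values vs the observed rest of the region (rank-sum).
    Transboundary PAs are excluded from national aggregation but retained
    in the region-wide computation. Nations below ``min_n`` are reported
    untested (NaN p-values).
    """
    if n_sims <= 0:
        raise DomainError("n_sims must be positive")
    unknown = set(metrics) - set(NULL_METRICS)
    if unknown:
        raise DomainError(f"unknown metrics: {sorted(unknown)}")
    if pairing not in ("mean", "median"):
        raise DomainError("pairing must be 'mean' or 'median'")
    rng = np.random.default_rng(seed)
    if weights is None:
        weights = ConservationWeights.from_occurrences(dataset.occurrences)

    P_obs = build_matrix(dataset.coverage, dataset.occurrences)
    species = P_obs.species_ids
    w = weights.aligned_to(species)
    areas = dataset.areas.to_numpy(dtype=float)
    observed = _metrics_from_probability(
        P_obs.values.to_numpy(), w, areas, metrics
    )

    # vectorized simulation loop
    freqs = np.asarray([occ.frequency for occ in dataset.occurrences], dtype=int)
    n_cells = len(dataset.coverage.cell_ids)
    if np.any(freqs > n_cells):
        raise DomainError("a species frequency exceeds the land-cell count")
    L = _log_complement(dataset.coverage.values.to_numpy(dtype=float))
    sims: dict[str, np.ndarray] = {
        m: np.empty((n_sims, len(dataset.pa_ids))) for m in metrics
    }
    for s in range(n_sims):
        occ = _random_occupancy(rng, n_cells, freqs)
        P_sim = _probability_from_occupancy(occ, L)
        vals = _metrics_from_probability(P_sim, w, areas, metrics)
        for m in metrics:
            sims[m][s] = vals[m]
    ensemble = NullModelEnsemble(
        values=sims, pa_ids=list(dataset.pa_ids), n_sims=n_sims, rng_seed=seed
    )

    nation = dataset.pa_nation().to_numpy(dtype=object)
    single = pd.notna(nation)
    rows = []
    for m in metrics:
        obs = observed[m]
        null_pair = (
            np.nanmean(sims[m], axis=0)
            if pairing == "mean"
            else np.nanmedian(sims[m], axis=0)
        )
        for nat in sorted({n for n in nation[single]}):
            in_nat = single & (nation == nat)
            rest = single & (nation != nat)
            obs_nat = obs[in_nat]
            p_null = signed_rank_test(obs_nat, null_pair[in_nat], min_n=min_n)
            p_rest = (
                rank_sum_test(obs_nat, obs[rest], min_n=min_n)
                if rest.any()
                else float("nan")
            )
            med_obs = float(np.nanmedian(obs_nat)) if in_nat.any() else np.nan
            med_null = float(np.nanmedian(null_pair[in_nat]))
            med_rest = float(np.nanmedian(obs[rest])) if rest.any() else np.nan
            iqr = _iqr(obs_nat)
            rows.append(
                {
                    "nation": nat,
                    "metric": m,
                    "n_pas": int(in_nat.sum()),
                    "observed_median": med_obs,
                    "observed_iqr_low": iqr[0],
                    "observed_iqr_high": iqr[1],
                    "null_median": med_null,
                    "rest_median": med_rest,
                    "p_vs_null": p_null,
                    "p_vs_rest": p_rest,
                    "direction_vs_null": float(np.sign(med_obs - med_null)),
                    "direction_vs_rest": float(np.sign(med_obs - med_rest)),
                    "sig_vs_null": bool(p_null < alpha) if np.isfinite(p_null) else False,
                    "sig_vs_rest": bool(p_rest < alpha) if np.isfinite(p_rest) else False,
                }
            )
    table = pd.DataFrame(rows)

    eu_rows = []
    for m in metrics:
        obs = observed[m]
        pool = (
            np.nanmedian(sims[m], axis=1) if per_sim_medians else sims[m].ravel()
        )
        o_iqr = _iqr(obs)
        n_iqr = _iqr(pool)
        eu_rows.append(
            {
                "metric": m,
                "observed_median": float(np.nanmedian(obs)),
                "observed_iqr_low": o_iqr[0],
                "observed_iqr_high": o_iqr[1],
                "null_median": float(np.nanmedian(pool)),
                "null_iqr_low": n_iqr[0],
                "null_iqr_high": n_iqr[1],
            }
        )
    observed_df = pd.DataFrame(observed, index=dataset.pa_ids).rename_axis("pa_id")
    return SensitivityReport(
        table=table,
        eu_summary=pd.DataFrame(eu_rows),
        ensemble=ensemble,
        observed=observed_df,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# leave-nations-out cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CrossValReport:
    sd: pd.DataFrame  # per PA x metric, NaN where undefined
    n_runs_retained: pd.Series  # per PA
    retained_nations: list[list[str]]
    n_runs: int
    n_keep: int


def cross_validate(
    dataset: AnalysisDataset,
    metrics: Sequence[str] = CROSSVAL_METRICS,
    n_runs: int = 1000,
    n_keep: int = 20,
    seed: int | None = None,
) -> CrossValReport:
    """Leave-nations-out uncertainty of the subset-dependent metrics.

    Each run keeps ``n_keep`` of the nations (chosen uniformly without
    replacement), drops the PAs and the occurrence records of the excluded
    nations, refits the SAR on the retained PAs and recomputes the
    dissimilarity summaries against the retained set only. Conservation
    weights are not recomputed (only under-reporting is being emulated, so
    the full-region weights remain the best rarity estimates — they do not
    enter these metrics). Transboundary PAs are excluded throughout.

    The per-PA standard deviation across the runs in which the PA was
    retained measures non-robustness to national reporting failure; it is
    NaN (missing) for PAs retained in fewer than two runs.
    """
    if n_runs <= 0:
        raise DomainError("n_runs must be positive")
    unknown = set(metrics) - set(CROSSVAL_METRICS)
    if unknown:
        raise DomainError(f"unknown cross-validation metrics: {sorted(unknown)}")
    nations = sorted(set(dataset.grid.df["nation"]))
    if n_keep >= len(nations):
        raise DomainError(
            f"n_keep={n_keep} must be smaller than the {len(nations)} nations"
        )
    rng = np.random.default_rng(seed)

    pa_nation = dataset.pa_nation()
    keep_pa = pa_nation.notna().to_numpy()
    pa_ids = [pid for pid, k in zip(dataset.pa_ids, keep_pa) if k]
    pa_nat = pa_nation.to_numpy(dtype=object)[keep_pa]
    areas = dataset.areas.to_numpy(dtype=float)[keep_pa]
    C = dataset.coverage.values.to_numpy(dtype=float)[keep_pa]
    L = _log_complement(C)

    cell_ids = dataset.coverage.cell_ids
    cell_nation = dataset.grid.nation_of().loc[cell_ids].to_numpy(dtype=object)
    cell_index = {cid: i for i, cid in enumerate(cell_ids)}
    occupancy = np.zeros((len(dataset.occurrences), len(cell_ids)))
    for s, occ in enumerate(dataset.occurrences):
        for cid in occ.occupied_cells:
            occupancy[s, cell_index[cid]] = 1.0

    n_pa = len(pa_ids)
    count = np.zeros(n_pa, dtype=int)
    acc = {m: np.zeros(n_pa) for m in metrics}
    acc2 = {m: np.zeros(n_pa) for m in metrics}
    nobs = {m: np.zeros(n_pa, dtype=int) for m in metrics}
    retained_lists: list[list[str]] = []

    for _ in range(n_runs):
        keep_nat = set(rng.choice(nations, size=n_keep, replace=False))
        retained_lists.append(sorted(keep_nat))
        pa_mask = np.array([n in keep_nat for n in pa_nat])
        if pa_mask.sum() < 3:
            continue  # too few PAs to refit a SAR this run
        cell_mask = np.array([n in keep_nat for n in cell_nation], dtype=float)
        occ_run = occupancy * cell_mask[None, :]
        P_run = _probability_from_occupancy(occ_run, L[pa_mask])
        vals = _metrics_from_probability(
            P_run, np.zeros(occupancy.shape[0]), areas[pa_mask], metrics
        )
        count[pa_mask] += 1
        for m in metrics:
            v = vals[m]
            good = np.isfinite(v)
            idx = np.flatnonzero(pa_mask)[good]
            acc[m][idx] += v[good]
            acc2[m][idx] += v[good] ** 2
            nobs[m][idx] += 1

    sd = {}
    for m in metrics:
        k = nobs[m]
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(k > 0, acc[m] / np.maximum(k, 1), np.nan)
            var = np.where(
                k > 1,
                (acc2[m] - np.maximum(k, 1) * mean**2) / np.maximum(k - 1, 1),
                np.nan,
            )
        sd[m] = np.sqrt(np.maximum(var, 0.0))
    sd_df = pd.DataFrame(sd, index=pa_ids).rename_axis("pa_id")
    return CrossValReport(
        sd=sd_df,
        n_runs_retained=pd.Series(count, index=pa_ids, name="n_runs_retained"),
        retained_nations=retained_lists,
        n_runs=n_runs,
        n_keep=n_keep,
    )


# ---------------------------------------------------------------------------
# spatially corrected correlation
# ---------------------------------------------------------------------------


@dataclass
class SpatialCorrelationResult:
    r: float
    p: float  # corrected for spatial autocorrelation
    effective_n: float
    n: int
    p_uncorrected: float
    n_classes: int


def _moran_by_class(z: np.ndarray, class_of: np.ndarray, n_classes: int) -> np.ndarray:
    """Moran's I of centred values for each distance class (binary weights)."""
    n = z.size
    denom = float((z**2).sum())
    out = np.zeros(n_classes)
    cross = np.outer(z, z)
    for c in range(n_classes):
        W = class_of == c
        s0 = W.sum()
        if s0 == 0 or denom == 0:
            out[c] = 0.0
        else:
            out[c] = (n / s0) * (cross[W].sum() / denom)
    return np.clip(out, -1.0, 1.0)


def spatial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    coords: np.ndarray | pd.DataFrame,
    n_classes: int | None = None,
    min_n: int = 10,
) -> SpatialCorrelationResult:
    """Pearson correlation with an autocorrelation-corrected t-test.

    The effective sample size is estimated from distance-class Moran
    correlograms of both variables (Sturges' rule on the pair count sets
    the default class number): with Rx, Ry the implied spatial correlation
    matrices, var(r) ~ tr(Rx Ry)/n^2 and n_eff = 1 + 1/var(r), capped at
    n. The t statistic then uses n_eff - 2 degrees of freedom.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    pts = np.asarray(coords, dtype=float)
    if xv.size != yv.size or pts.shape[0] != xv.size:
        raise DomainError("x, y and coords must have matching lengths")
    keep = np.isfinite(xv) & np.isfinite(yv)
    xv, yv, pts = xv[keep], yv[keep], pts[keep]
    n = xv.size
    if n < min_n:
        raise ValidationError(f"need >= {min_n} PAs for spatial correlation")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DomainError("zero variance: correlation undefined")

    r = float(np.corrcoef(xv, yv)[0, 1])
    t_unc = r * np.sqrt((n - 2) / max(1 - r**2, 1e-300))
    p_unc = float(2 * stats.t.sf(abs(t_unc), n - 2))

    D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    n_pairs = n * (n - 1) // 2
    if n_classes is None:
        n_classes = int(np.ceil(1 + np.log2(n_pairs)))  # Sturges' rule
    dmax = D.max()
    edges = np.linspace(0.0, dmax * (1 + 1e-12), n_classes + 1)
    class_of = np.digitize(D, edges[1:-1])
    np.fill_diagonal(class_of, -1)

    zx = xv - xv.mean()
    zy = yv - yv.mean()
    ix = _moran_by_class(zx, class_of, n_classes)
    iy = _moran_by_class(zy, class_of, n_classes)
    Rx = ix[np.clip(class_of, 0, None)]
    Ry = iy[np.clip(class_of, 0, None)]
    np.fill_diagonal(Rx, 1.0)
    np.fill_diagonal(Ry, 1.0)
    var_r = max(float((Rx * Ry).sum()) / n**2, 1.0 / n**2)
    ess = min(float(n), 1.0 + 1.0 / var_r)
    if ess <= 2:
        return SpatialCorrelationResult(r, float("nan"), ess, n, p_unc, n_classes)
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((ess - 2) / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), ess - 2))
    return SpatialCorrelationResult(r, p, ess, n, p_unc, n_classes)
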