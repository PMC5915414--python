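"""Probabilistic assignment of species to protected areas.

With a species present in ``n`` grid cells that a PA covers with
fractions c_1 ... c_n, and treating presence in each covered cell part as
independent, the probability that the species occurs somewhere inside the
PA is the chain-rule complement product

    p = 1 - (1 - c_1)(1 - c_2) ... (1 - c_n).

Coverage fractions double as per-cell presence probabilities because the
occurrence data carry no sub-cell information: a species reported from a
cell is assumed equally likely to sit in any part of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data_io import CoverageMatrix, SpeciesOccurrence
from .errors import DomainError, JoinError

__all__ = [
    "OccurrenceProbabilityMatrix",
    "assign_probability",
    "build_matrix",
]

# log1p(-c) for c == 1 would be -inf, which poisons matmuls (0 * -inf = nan);
# -800 underflows expm1 to -1 exactly, giving p == 1.
_LOG_FLOOR = -800.0


def assign_probability(coverages: Sequence[float]) -> float:
    """Cumulative probability that a species occurs in a PA.

    Parameters
    ----------
    coverages : sequence of float
        PA coverage fraction of each occupied grid cell, each in [0, 1].
        An empty sequence returns 0 (the species occupies no covered cell).
    """
    c = np.asarray(list(coverages), dtype=float)
    if c.size == 0:
        return 0.0
    if np.any((c < 0) | (c > 1)) or np.any(~np.isfinite(c)):
        raise DomainError("coverage fractions must lie in [0, 1]")
    if np.any(c == 1.0):
        return 1.0  # a fully covered occupied cell makes presence certain
    return float(1.0 - np.prod(1.0 - c))


def _log_complement(coverage: np.ndarray) -> np.ndarray:
    """Elementwise log(1 - c) with c == 1 floored for safe matmul use."""
    with np.errstate(divide="ignore"):
        out = np.log1p(-np.clip(coverage, 0.0, 1.0))
    return np.maximum(out, _LOG_FLOOR)


def _probability_from_occupancy(
    occupancy: np.ndarray, log_complement: np.ndarray
) -> np.ndarray:
    """(n_species x n_cells) 0/1 occupancy times (n_pa x n_cells) log(1-c)
    -> (n_pa x n_species) probability matrix, in one matmul."""
    log_miss = occupancy.astype(float) @ log_complement.T  # (n_sp, n_pa)
    return -np.expm1(np.maximum(log_miss, _LOG_FLOOR)).T


@dataclass
class OccurrenceProbabilityMatrix:
    """(pa_id x species_id) cumulative presence probabilities.

    ``n_cells_used`` counts, per entry, the occupied cells with positive
    coverage that contributed to the probability. ``species_outside`` lists
    species whose probability is 0 for every PA (they occur in the grid but
    in no cell any PA touches).
    """

    values: pd.DataFrame
    n_cells_used: pd.DataFrame
    species_outside: list[str]

    @property
    def pa_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_wide_csv(self, path: str | Path) -> None:
        self.values.rename_axis("pa_id").to_csv(path)

    def to_long_csv(self, path: str | Path) -> None:
        long = self.values.rename_axis("pa_id").reset_index().melt(
            id_vars="pa_id", var_name="species_id", value_name="p"
        )
        n = self.n_cells_used.rename_axis("pa_id").reset_index().melt(
            id_vars="pa_id", var_name="species_id", value_name="n_cells_used"
        )
        long.merge(n, on=["pa_id", "species_id"]).to_csv(path, index=False)


def build_matrix(
    coverage: CoverageMatrix, occurrences: Sequence[SpeciesOccurrence]
) -> OccurrenceProbabilityMatrix:
    """Assemble the PA x species probability matrix from coverage rows.

    Every occupied cell id must resolve in the coverage matrix columns;
    an unknown id raises :class:`JoinError`.
    """
    cell_index = {cid: i for i, cid in enumerate(coverage.cell_ids)}
    C = coverage.values.to_numpy(dtype=float)
    n_pa = C.shape[0]
    n_sp = len(occurrences)
    occupancy = np.zeros((n_sp, C.shape[1]))
    for s, occ in enumerate(occurrences):
        for cid in occ.occupied_cells:
            if cid not in cell_index:
                raise JoinError(
                    f"species {occ.species_id!r}: cell {cid!r} not in coverage index"
                )
            occupancy[s, cell_index[cid]] = 1.0
    if n_pa and n_sp:
        P = _probability_from_occupancy(occupancy, _log_complement(C))
        n_used = (occupancy @ (C > 0).T.astype(float)).T.astype(int)
    else:
        P = np.zeros((n_pa, n_sp))
        n_used = np.zeros((n_pa, n_sp), dtype=int)
    species = [occ.species_id for occ in occurrences]
    values = pd.DataFrame(P, index=coverage.pa_ids, columns=species)
    counts = pd.DataFrame(n_used, index=coverage.pa_ids, columns=species)
    outside = [sp for sp, tot in values.sum(axis=0).items() if tot == 0.0]
    return OccurrenceProbabilityMatrix(
        values=values, n_cells_used=counts, species_outside=outside
    )
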