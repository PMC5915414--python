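"""Seeded synthetic landscapes with the statistical structure the
analysis assumes.

A scenario is a rectangular lattice of square land cells partitioned into
contiguous rectangular nations; protected areas of log-uniformly
distributed size placed inside (or, optionally, across) nations; a
species pool with a right-skewed, discrete power-law frequency spectrum
and optional spatial aggregation of each species around a random centre;
and configurable per-nation under-reporting that deletes a fraction of a
nation's occurrence records. The generator returns, besides the dataset,
a truth record (pre-bias occurrences, intended frequencies, biased
nations) that sensitivity tests can score recovery against.

Three named presets ship with the package:

* ``clean``   — the unbiased study conditions (12 nations, 10 PAs each,
  PA areas log-uniform 150-750 km^2, 350 species, uniform placement);
* ``biased``  — the same, with half of one nation's records deleted;
* ``nested-pas`` — allows overlapping PAs (MAB reserves enclosing
  national parks), with a MAB placed over each NP in part of the pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box

from .core_data_io import (
    AnalysisDataset,
    GridCellTable,
    ProtectedArea,
    SpeciesOccurrence,
    build_dataset,
    make_circular_buffer,
)
from .errors import DomainError, PlacementError, ValidationError

__all__ = [
    "GridConfig",
    "PAConfig",
    "SpeciesConfig",
    "ScenarioConfig",
    "ScenarioTruth",
    "generate_scenario",
    "generate_dataset",
    "apply_reporting_bias",
    "preset_scenario",
    "PRESETS",
]


@dataclass
class GridConfig:
    nx: int = 48
    ny: int = 36
    cell_side: float = 10.0  # km


@dataclass
class PAConfig:
    per_nation: int = 10
    area_range: tuple[float, float] = (150.0, 750.0)  # km^2, log-uniform
    shape: str = "circle"  # or "rectangle"
    transboundary_fraction: float = 0.0
    allow_overlap: bool = False
    mab_overlay_fraction: float = 0.0  # fraction of NPs nested inside a MAB
    n_vertices: int = 256
    max_retries: int = 200


@dataclass
class SpeciesConfig:
    n_species: int = 350
    freq_exponent: float = 1.3  # P(f) ~ f^-exponent
    max_frequency: int = 1500
    frequencies: list[int] | None = None  # overrides the power law
    aggregation_spread: float | None = None  # km; None = uniform placement


@dataclass
class ScenarioConfig:
    grid: GridConfig = field(default_factory=GridConfig)
    n_nations: int = 12
    pas: PAConfig = field(default_factory=PAConfig)
    species: SpeciesConfig = field(default_factory=SpeciesConfig)
    bias: dict[str, float] = field(default_factory=dict)  # nation -> deletion fraction
    seed: int = 0

    def validate(self) -> None:
        if self.grid.nx <= 0 or self.grid.ny <= 0 or self.grid.cell_side <= 0:
            raise DomainError("grid dimensions must be positive")
        if self.n_nations < 1 or self.n_nations > self.grid.nx * self.grid.ny:
            raise DomainError("nation count must fit in the grid")
        if self.pas.per_nation < 0:
            raise DomainError("PA count must be non-negative")
        if not (0 < self.pas.area_range[0] <= self.pas.area_range[1]):
            raise DomainError("PA area range must be positive and ordered")
        if self.species.n_species < 0:
            raise DomainError("species count must be non-negative")
        for nat, frac in self.bias.items():
            if not 0.0 <= frac <= 1.0:
                raise DomainError(f"bias fraction for {nat!r} outside [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScenarioTruth:
    """Ground truth kept aside for sensitivity tests."""

    pre_bias_occurrences: list[SpeciesOccurrence]
    frequencies: pd.Series  # intended (pre-bias) occupied-cell counts
    biased_nations: dict[str, float]
    deleted_records: dict[str, int]  # nation -> records removed
    seed: int


def _nation_code(i: int) -> str:
    return f"N{i:02d}"


def _nation_layout(n_nations: int) -> tuple[int, list[int]]:
    """Split ``n_nations`` into r horizontal bands with per-band column
    counts as square-ish as possible; every nation is a rectangle."""
    r = max(1, round(math.sqrt(n_nations)))
    while n_nations % r and r > 1:
        r -= 1
    if n_nations % r == 0:
        return r, [n_nations // r] * r
    base = n_nations // r
    counts = [base] * r
    for i in range(n_nations - base * r):
        counts[i] += 1
    return r, counts


def _make_grid(config: ScenarioConfig) -> GridCellTable:
    g = config.grid
    rbands, cols_per_band = _nation_layout(config.n_nations)
    band_edges = np.linspace(0, g.ny, rbands + 1).round().astype(int)
    rows = []
    nation_idx = 0
    band_start = {}
    for b in range(rbands):
        band_start[b] = nation_idx
        nation_idx += cols_per_band[b]
    for iy in range(g.ny):
        b = int(np.searchsorted(band_edges[1:], iy, side="right"))
        ncols = cols_per_band[b]
        col_edges = np.linspace(0, g.nx, ncols + 1).round().astype(int)
        for ix in range(g.nx):
            k = int(np.searchsorted(col_edges[1:], ix, side="right"))
            nation = _nation_code(band_start[b] + k)
            cell = box(
                ix * g.cell_side,
                iy * g.cell_side,
                (ix + 1) * g.cell_side,
                (iy + 1) * g.cell_side,
            )
            rows.append(
                {
                    "cell_id": f"c{ix:03d}_{iy:03d}",
                    "nation": nation,
                    "is_land": True,
                    "geometry": cell,
                }
            )
    return GridCellTable(pd.DataFrame(rows))


def _pa_shape(
    shape: str,
    center: tuple[float, float],
    area: float,
    rng: np.random.Generator,
    n_vertices: int,
) -> Polygon:
    if shape == "circle":
        return make_circular_buffer(Point(center), area, n_vertices)
    if shape == "rectangle":
        aspect = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
        w = math.sqrt(area * aspect)
        h = area / w
        return box(center[0] - w / 2, center[1] - h / 2, center[0] + w / 2, center[1] + h / 2)
    raise DomainError(f"unknown PA shape {shape!r}")


def _place_pas(
    config: ScenarioConfig, grid: GridCellTable, rng: np.random.Generator
) -> list[ProtectedArea]:
    g = config.grid
    pc = config.pas
    nation_bounds: dict[str, tuple[float, float, float, float]] = {}
    for nat, grp in grid.df.groupby("nation"):
        xs = [geom.bounds for geom in grp["geometry"]]
        nation_bounds[nat] = (
            min(b[0] for b in xs),
            min(b[1] for b in xs),
            max(b[2] for b in xs),
            max(b[3] for b in xs),
        )
    grid_bbox = (
        0.0,
        0.0,
        g.nx * g.cell_side,
        g.ny * g.cell_side,
    )
    cell_centres = np.array(
        [(geom.centroid.x, geom.centroid.y) for geom in grid.df["geometry"]]
    )
    cell_nations = grid.df["nation"].to_numpy(dtype=object)

    pas: list[ProtectedArea] = []
    placed: list[Polygon] = []
    counter = 0
    for nat in sorted(nation_bounds):
        x0, y0, x1, y1 = nation_bounds[nat]
        for _ in range(pc.per_nation):
            counter += 1
            pa_id = f"PA{counter:04d}"
            transboundary_intent = rng.random() < pc.transboundary_fraction
            geom = None
            for _attempt in range(pc.max_retries):
                area = float(
                    np.exp(rng.uniform(*np.log(np.asarray(pc.area_range))))
                )
                half = math.sqrt(area / math.pi) if pc.shape == "circle" else math.sqrt(area * 2) / 2
                if transboundary_intent:
                    # centre on the nation's boundary so the PA straddles it
                    edge = rng.integers(4)
                    if edge == 0:
                        cx, cy = x0, rng.uniform(y0, y1)
                    elif edge == 1:
                        cx, cy = x1, rng.uniform(y0, y1)
                    elif edge == 2:
                        cx, cy = rng.uniform(x0, x1), y0
                    else:
                        cx, cy = rng.uniform(x0, x1), y1
                else:
                    lo_x, hi_x = x0 + half, x1 - half
                    lo_y, hi_y = y0 + half, y1 - half
                    if lo_x > hi_x or lo_y > hi_y:
                        continue  # PA too large for this nation; resample area
                    cx, cy = rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)
                cand = _pa_shape(pc.shape, (cx, cy), area, rng, pc.n_vertices)
                bx0, by0, bx1, by1 = cand.bounds
                if (
                    bx0 < grid_bbox[0] - 1e-9
                    or by0 < grid_bbox[1] - 1e-9
                    or bx1 > grid_bbox[2] + 1e-9
                    or by1 > grid_bbox[3] + 1e-9
                ):
                    continue
                if not pc.allow_overlap and any(
                    cand.intersects(p) for p in placed
                ):
                    continue
                geom = cand
                break
            if geom is None:
                raise PlacementError(
                    f"could not place PA in nation {nat} after "
                    f"{pc.max_retries} retries (areas {pc.area_range} km^2)"
                )
            # nations of a PA = nations of cells whose centres it covers
            import shapely

            covered = shapely.contains_xy(geom, cell_centres[:, 0], cell_centres[:, 1])
            nations = set(cell_nations[covered]) or {nat}
            placed.append(geom)
            pas.append(
                ProtectedArea(
                    pa_id=pa_id,
                    designation="NP",
                    nations=frozenset(nations),
                    reported_area=geom.area,
                    geometry=geom,
                    transboundary=len(nations) > 1,
                )
            )
    return pas


def _overlay_mabs(
    pas: list[ProtectedArea], rng: np.random.Generator, fraction: float = 0.3
) -> list[ProtectedArea]:
    """Add MAB reserves enclosing a fraction of the NPs (nested PAs)."""
    extra = []
    n = len(pas)
    chosen = rng.choice(n, size=max(1, int(fraction * n)), replace=False)
    for i, idx in enumerate(sorted(chosen), start=1):
        np_pa = pas[idx]
        geom = np_pa.geometry.buffer(np.sqrt(np_pa.reported_area) * 0.2)
        extra.append(
            ProtectedArea(
                pa_id=f"MAB{i:04d}",
                designation="MAB",
                nations=np_pa.nations,
                reported_area=geom.area,
                geometry=geom,
                transboundary=np_pa.transboundary,
            )
        )
    return pas + extra


def _sample_frequencies(
    sc: SpeciesConfig, n_land: int, rng: np.random.Generator
) -> np.ndarray:
    if sc.frequencies is not None:
        freqs = np.asarray(sc.frequencies, dtype=int)
        if len(freqs) != sc.n_species:
            raise DomainError("explicit frequency list length != n_species")
    else:
        fmax = min(sc.max_frequency, n_land)
        support = np.arange(1, fmax + 1)
        pmf = support.astype(float) ** (-sc.freq_exponent)
        pmf /= pmf.sum()
        freqs = rng.choice(support, size=sc.n_species, p=pmf)
    if np.any(freqs < 1) or np.any(freqs > n_land):
        raise DomainError("species frequencies must lie in [1, n_land_cells]")
    return freqs


def _place_species(
    sc: SpeciesConfig,
    grid: GridCellTable,
    freqs: np.ndarray,
    rng: np.random.Generator,
) -> list[SpeciesOccurrence]:
    land = grid.land
    cell_ids = land["cell_id"].to_numpy(dtype=object)
    centres = np.array([(g.centroid.x, g.centroid.y) for g in land["geometry"]])
    n = len(cell_ids)
    out = []
    for s, f in enumerate(freqs):
        if sc.aggregation_spread is None:
            idx = rng.choice(n, size=int(f), replace=False)
        else:
            # truncated Gaussian kernel around a random centre cell;
            # Gumbel-top-k draws a weighted sample without replacement
            centre = centres[rng.integers(n)]
            d2 = ((centres - centre) ** 2).sum(axis=1)
            logw = -d2 / (2 * sc.aggregation_spread**2)
            keys = logw + rng.gumbel(size=n)
            idx = np.argpartition(-keys, int(f) - 1)[: int(f)]
        out.append(
            SpeciesOccurrence(
                species_id=f"sp{s:04d}",
                taxon_group="other",
                occupied_cells=frozenset(cell_ids[idx]),
            )
        )
    return out


def apply_reporting_bias(
    occurrences: Sequence[SpeciesOccurrence],
    grid: GridCellTable,
    bias_map: Mapping[str, float],
    rng: np.random.Generator,
) -> tuple[list[SpeciesOccurrence], dict[str, int]]:
    """Delete each (species, cell) record in a biased nation independently
    with that nation's deletion probability. Records are never added.

    Returns the thinned occurrence list (species losing every record are
    dropped) and the per-nation count of deleted records.
    """
    nations = set(grid.df["nation"])
    unknown = set(bias_map) - nations
    if unknown:
        raise ValidationError(f"bias for unknown nations: {sorted(unknown)}")
    for nat, frac in bias_map.items():
        if not 0.0 <= frac <= 1.0:
            raise DomainError(f"bias fraction for {nat!r} outside [0, 1]")
    nation_of = grid.nation_of()
    deleted: dict[str, int] = {nat: 0 for nat in bias_map}
    out = []
    for occ in occurrences:
        kept = []
        for cid in sorted(occ.occupied_cells):
            frac = bias_map.get(nation_of[cid], 0.0)
            if frac > 0.0 and rng.random() < frac:
                deleted[nation_of[cid]] += 1
            else:
                kept.append(cid)
        if kept:
            out.append(
                SpeciesOccurrence(
                    species_id=occ.species_id,
                    taxon_group=occ.taxon_group,
                    occupied_cells=frozenset(kept),
                )
            )
    return out, deleted


def generate_scenario(
    config: ScenarioConfig,
) -> tuple[GridCellTable, list[SpeciesOccurrence], list[ProtectedArea], ScenarioTruth]:
    """Generate a full synthetic dataset; identical output for equal seeds."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = _make_grid(config)
    pas = _place_pas(config, grid, rng)
    if config.pas.mab_overlay_fraction > 0:
        pas = _overlay_mabs(pas, rng, config.pas.mab_overlay_fraction)
    freqs = _sample_frequencies(config.species, len(grid.land), rng)
    occurrences = _place_species(config.species, grid, freqs, rng)
    truth_freq = pd.Series(
        {o.species_id: o.frequency for o in occurrences}, dtype=int, name="frequency"
    )
    biased, deleted = apply_reporting_bias(occurrences, grid, config.bias, rng)
    truth = ScenarioTruth(
        pre_bias_occurrences=occurrences,
        frequencies=truth_freq,
        biased_nations=dict(config.bias),
        deleted_records=deleted,
        seed=config.seed,
    )
    return grid, biased, pas, truth


def generate_dataset(
    config: ScenarioConfig,
) -> tuple[AnalysisDataset, ScenarioTruth]:
    """Convenience wrapper: generate a scenario and assemble the analysis
    dataset (coverage matrix included)."""
    grid, occurrences, pas, truth = generate_scenario(config)
    ds = build_dataset(grid, occurrences, pas, n_vertices=config.pas.n_vertices)
    return ds, truth


PRESETS = ("clean", "biased", "nested-pas")


def preset_scenario(name: str, seed: int = 0) -> ScenarioConfig:
    """Named preset scenarios (see module docstring)."""
    if name == "clean":
        return ScenarioConfig(seed=seed)
    if name == "biased":
        return ScenarioConfig(seed=seed, bias={_nation_code(3): 0.5})
    if name == "nested-pas":
        cfg = ScenarioConfig(seed=seed)
        cfg.pas.allow_overlap = True
        cfg.pas.mab_overlay_fraction = 0.3
        return cfg
    raise DomainError(f"unknown preset {name!r}; choose from {PRESETS}")
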