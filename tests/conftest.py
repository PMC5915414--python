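import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from pauniq.core_data_io import (
    AnalysisDataset,
    GridCellTable,
    ProtectedArea,
    SpeciesOccurrence,
    build_dataset,
)


def square_grid(nx, ny, side=10.0, nation="AAA", origin=(0.0, 0.0)):
    """Plain rectangular all-land grid, one nation unless nation is a callable
    mapping (ix, iy) -> code."""
    rows = []
    x0, y0 = origin
    for iy in range(ny):
        for ix in range(nx):
            nat = nation(ix, iy) if callable(nation) else nation
            rows.append(
                {
                    "cell_id": f"c{ix:03d}_{iy:03d}",
                    "nation": nat,
                    "is_land": True,
                    "geometry": box(
                        x0 + ix * side,
                        y0 + iy * side,
                        x0 + (ix + 1) * side,
                        y0 + (iy + 1) * side,
                    ),
                }
            )
    return GridCellTable(pd.DataFrame(rows))


def clone_nations_dataset(n_nations=25):
    """Every nation an identical translated copy of the same landscape.

    5 x 5 nations of 6 x 6 cells; three same-sized PAs per nation at the
    same relative positions; every species occupies the same relative cell
    in every nation. Any equal-sized subset of nations therefore yields
    identical metric values, which pins leave-nations-out SDs at zero.
    """
    assert n_nations == 25
    from pauniq.core_data_io import make_circular_buffer
    from shapely.geometry import Point

    grid = square_grid(
        30, 30, nation=lambda ix, iy: f"N{(iy // 6) * 5 + ix // 6:02d}"
    )
    pas = []
    occs = {}
    for by in range(5):
        for bx in range(5):
            nat = f"N{by * 5 + bx:02d}"
            ox, oy = bx * 60.0, by * 60.0
            for k, (rx, ry, area) in enumerate(
                [(15, 15, 200.0), (45, 15, 450.0), (30, 40, 800.0)]
            ):
                pas.append(
                    ProtectedArea(
                        pa_id=f"PA_{nat}_{k}",
                        designation="NP",
                        nations=frozenset({nat}),
                        reported_area=area,
                        geometry=make_circular_buffer(
                            Point(ox + rx, oy + ry), area
                        ),
                    )
                )
            for cy in range(6):
                for cx in range(6):
                    sid = f"sp_{cx}_{cy}"
                    cell = f"c{bx * 6 + cx:03d}_{by * 6 + cy:03d}"
                    occs.setdefault(sid, set()).add(cell)
    occurrences = [
        SpeciesOccurrence(sid, frozenset(cells)) for sid, cells in sorted(occs.items())
    ]
    return build_dataset(grid, occurrences, pas)


@pytest.fixture
def grid4():
    """2 x 2 grid of 10 km cells, all land, one nation."""
    return square_grid(2, 2)


@pytest.fixture
def tiny_dataset(grid4):
    """Two PAs with hand-constructed coverages and two species.

    PA_A covers 20% of c000_000 and 50% of c001_000 (rectangles), so a
    species occupying both cells has p = 1-(1-0.2)(1-0.5) = 0.6.
    PA_B covers all of c000_001.
    """
    pa_a = ProtectedArea(
        pa_id="PA_A",
        designation="NP",
        nations=frozenset({"AAA"}),
        reported_area=70.0,
        geometry=box(0, 0, 2, 10).union(box(10, 0, 15, 10)),
    )
    pa_b = ProtectedArea(
        pa_id="PA_B",
        designation="MAB",
        nations=frozenset({"AAA"}),
        reported_area=100.0,
        geometry=box(0, 10, 10, 20),
    )
    occurrences = [
        SpeciesOccurrence("sp_wide", frozenset({"c000_000", "c001_000"}), "bird"),
        SpeciesOccurrence("sp_local", frozenset({"c000_001"}), "mammal"),
    ]
    return build_dataset(grid4, occurrences, [pa_a, pa_b])
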