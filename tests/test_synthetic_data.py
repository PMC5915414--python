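import numpy as np
import pytest
import shapely
from scipy import stats

from pauniq.diversity_metrics import species_frequencies
from pauniq.errors import DomainError, PlacementError, ValidationError
from pauniq.synthetic_data import (
    GridConfig,
    PAConfig,
    ScenarioConfig,
    SpeciesConfig,
    apply_reporting_bias,
    generate_scenario,
    preset_scenario,
)
from conftest import square_grid


def small_config(seed=7, **kwargs):
    cfg = ScenarioConfig(
        grid=GridConfig(nx=20, ny=20),
        n_nations=4,
        pas=PAConfig(per_nation=2, area_range=(80.0, 400.0)),
        species=SpeciesConfig(n_species=50, max_frequency=100),
        seed=seed,
    )
    for k, v in kwargs.items():
        setattr(cfg, k, v)
    return cfg


class TestGeneration:
    def test_determinism(self):
        g1, o1, p1, t1 = generate_scenario(small_config())
        g2, o2, p2, t2 = generate_scenario(small_config())
        assert g1.df["nation"].tolist() == g2.df["nation"].tolist()
        assert [(o.species_id, o.occupied_cells) for o in o1] == [
            (o.species_id, o.occupied_cells) for o in o2
        ]
        assert [shapely.to_wkt(a.geometry) for a in p1] == [
            shapely.to_wkt(b.geometry) for b in p2
        ]
        assert t1.frequencies.equals(t2.frequencies)

    def test_structure_and_referential_integrity(self):
        grid, occs, pas, truth = generate_scenario(small_config())
        assert len(pas) == 8  # 4 nations x 2 PAs
        assert grid.df["nation"].nunique() == 4
        cell_ids = set(grid.cell_ids)
        for occ in occs:
            assert occ.occupied_cells <= cell_ids
        minx, miny, maxx, maxy = (0, 0, 200, 200)
        for pa in pas:
            bx0, by0, bx1, by1 = pa.geometry.bounds
            assert bx0 >= minx - 1e-9 and by0 >= miny - 1e-9
            assert bx1 <= maxx + 1e-9 and by1 <= maxy + 1e-9

    def test_pas_do_not_overlap_by_default(self):
        _, _, pas, _ = generate_scenario(small_config(seed=11))
        for i in range(len(pas)):
            for j in range(i + 1, len(pas)):
                assert not pas[i].geometry.intersects(pas[j].geometry)

    def test_frequencies_ground_truth_without_bias(self):
        _, occs, _, truth = generate_scenario(small_config())
        observed = species_frequencies(occs)
        assert observed.sort_index().equals(truth.frequencies.sort_index())

    def test_oversized_pa_raises_placement_error(self):
        cfg = small_config()
        # nation blocks are 100 km x 100 km = 10^4 km^2; a 9000 km^2 circle
        # (radius ~53.5 km) cannot fit inside
        cfg.pas = PAConfig(per_nation=1, area_range=(9000.0, 9000.0))
        with pytest.raises(PlacementError):
            generate_scenario(cfg)

    def test_transboundary_placement(self):
        cfg = small_config(seed=3)
        cfg.pas = PAConfig(
            per_nation=2, area_range=(300.0, 300.0), transboundary_fraction=1.0
        )
        _, _, pas, _ = generate_scenario(cfg)
        assert all(pa.transboundary for pa in pas)
        assert all(len(pa.nations) > 1 for pa in pas)

    def test_aggregated_species_are_clustered(self):
        tight = small_config()
        tight.species = SpeciesConfig(
            n_species=30, max_frequency=30, aggregation_spread=15.0
        )
        loose = small_config()
        loose.species = SpeciesConfig(n_species=30, max_frequency=30)

        def mean_spread(occs, grid):
            centres = {
                cid: (g.centroid.x, g.centroid.y)
                for cid, g in zip(grid.cell_ids, grid.df["geometry"])
            }
            spreads = []
            for occ in occs:
                if occ.frequency < 3:
                    continue
                pts = np.array([centres[c] for c in occ.occupied_cells])
                spreads.append(pts.std(axis=0).mean())
            return np.mean(spreads)

        gt, ot, _, _ = generate_scenario(tight)
        gl, ol, _, _ = generate_scenario(loose)
        assert mean_spread(ot, gt) < mean_spread(ol, gl)

    def test_power_law_frequency_spectrum(self):
        # chi-square goodness of fit of sampled frequencies against the
        # discrete power law should hold in nearly all seeds
        fmax, alpha, n_species = 100, 2.0, 500
        support = np.arange(1, fmax + 1)
        pmf = support.astype(float) ** -alpha
        pmf /= pmf.sum()
        passed = 0
        for seed in range(20):
            cfg = small_config(seed=seed)
            cfg.species = SpeciesConfig(
                n_species=n_species, freq_exponent=alpha, max_frequency=fmax
            )
            _, _, _, truth = generate_scenario(cfg)
            freqs = truth.frequencies.to_numpy()
            # pool the tail so expected counts stay reasonable
            edges = [1, 2, 3, 4, 6, 10, fmax + 1]
            obs, _ = np.histogram(freqs, bins=edges)
            exp = np.array(
                [
                    pmf[(support >= lo) & (support < hi)].sum()
                    for lo, hi in zip(edges[:-1], edges[1:])
                ]
            ) * n_species
            p = stats.chisquare(obs, exp).pvalue
            passed += p > 0.01
        assert passed >= 18


class TestReportingBias:
    def _setup(self):
        grid = square_grid(
            10, 10, nation=lambda ix, iy: "EAST" if ix >= 5 else "WEST"
        )
        rng = np.random.default_rng(0)
        cells = np.array(grid.cell_ids, dtype=object)
        from pauniq.core_data_io import SpeciesOccurrence

        occs = [
            SpeciesOccurrence(
                f"sp{i}", frozenset(cells[rng.choice(100, 20, replace=False)])
            )
            for i in range(50)
        ]
        return grid, occs

    def test_zero_bias_is_identity(self):
        grid, occs = self._setup()
        out, deleted = apply_reporting_bias(
            occs, grid, {"EAST": 0.0}, np.random.default_rng(1)
        )
        assert [o.occupied_cells for o in out] == [o.occupied_cells for o in occs]
        assert deleted == {"EAST": 0}

    def test_full_bias_removes_all_nation_records(self):
        grid, occs = self._setup()
        east = {c for c in grid.cell_ids if grid.nation_of()[c] == "EAST"}
        out, _ = apply_reporting_bias(
            occs, grid, {"EAST": 1.0}, np.random.default_rng(1)
        )
        for occ in out:
            assert not (occ.occupied_cells & east)

    def test_half_bias_within_binomial_bound(self):
        grid, occs = self._setup()
        east = {c for c in grid.cell_ids if grid.nation_of()[c] == "EAST"}
        n_east = sum(len(o.occupied_cells & east) for o in occs)
        out, deleted = apply_reporting_bias(
            occs, grid, {"EAST": 0.5}, np.random.default_rng(2)
        )
        retained = sum(len(o.occupied_cells & east) for o in out)
        assert retained + deleted["EAST"] == n_east
        bound = 3 * np.sqrt(n_east * 0.25)
        assert abs(retained - n_east / 2) <= bound

    def test_unknown_nation_rejected(self):
        grid, occs = self._setup()
        with pytest.raises(ValidationError):
            apply_reporting_bias(occs, grid, {"NOPE": 0.5}, np.random.default_rng(0))

    def test_bad_fraction_rejected(self):
        grid, occs = self._setup()
        with pytest.raises(DomainError):
            apply_reporting_bias(occs, grid, {"EAST": 1.5}, np.random.default_rng(0))


class TestPresets:
    def test_presets_exist_and_differ(self):
        clean = preset_scenario("clean", seed=1)
        biased = preset_scenario("biased", seed=1)
        nested = preset_scenario("nested-pas", seed=1)
        assert clean.bias == {}
        assert biased.bias and all(0 < v <= 1 for v in biased.bias.values())
        assert nested.pas.allow_overlap
        with pytest.raises(DomainError):
            preset_scenario("nope")

    def test_nested_preset_produces_mabs_over_nps(self):
        cfg = preset_scenario("nested-pas", seed=2)
        cfg.grid = GridConfig(nx=24, ny=24)
        cfg.n_nations = 4
        cfg.pas.per_nation = 3
        cfg.species.n_species = 20
        _, _, pas, _ = generate_scenario(cfg)
        mabs = [pa for pa in pas if pa.designation == "MAB"]
        nps = [pa for pa in pas if pa.designation == "NP"]
        assert mabs and nps
        assert any(
            m.geometry.contains(n.geometry) for m in mabs for n in nps
        )
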