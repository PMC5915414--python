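import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from pauniq.core_data_io import ProtectedArea, SpeciesOccurrence, build_dataset
from pauniq.errors import DomainError, ValidationError
from pauniq.sensitivity import (
    cross_validate,
    randomize_occurrences,
    rank_sum_test,
    run_null_model_analysis,
    signed_rank_test,
    spatial_correlation,
)
from conftest import clone_nations_dataset, square_grid
from oracles import rank_sum_p_enumeration, signed_rank_p_enumeration


class TestRandomization:
    def _occs(self):
        return [
            SpeciesOccurrence("a", frozenset({"c000_000"})),
            SpeciesOccurrence("b", frozenset({"c000_000", "c001_000", "c000_001"})),
        ]

    def test_frequencies_conserved_on_land(self, grid4):
        rng = np.random.default_rng(0)
        land = grid4.land_cell_ids
        for _ in range(20):
            rand = randomize_occurrences(self._occs(), land, rng)
            for orig, new in zip(self._occs(), rand):
                assert new.frequency == orig.frequency
                assert new.occupied_cells <= set(land)

    def test_full_grid_frequency_returns_everything(self, grid4):
        occ = [SpeciesOccurrence("full", frozenset(grid4.land_cell_ids))]
        rand = randomize_occurrences(
            occ, grid4.land_cell_ids, np.random.default_rng(1)
        )
        assert rand[0].occupied_cells == set(grid4.land_cell_ids)

    def test_seed_determinism(self, grid4):
        land = grid4.land_cell_ids
        a = randomize_occurrences(self._occs(), land, np.random.default_rng(7))
        b = randomize_occurrences(self._occs(), land, np.random.default_rng(7))
        assert [o.occupied_cells for o in a] == [o.occupied_cells for o in b]

    def test_frequency_exceeding_cells_rejected(self, grid4):
        occ = [SpeciesOccurrence("x", frozenset({"a", "b", "c"}))]
        with pytest.raises(DomainError):
            randomize_occurrences(occ, ["a", "b"], np.random.default_rng(0))


class TestSignedRankTest:
    def test_all_positive_n6_exact(self):
        obs = [1.0, 2, 3, 4, 5, 6]
        assert signed_rank_test(obs, [0.0] * 6) == pytest.approx(2 / 64)

    def test_symmetric_differences_not_significant(self):
        p = signed_rank_test([1.0, -1.0, 2.0, -2.0, 0.5, -0.5],
                             [0.0] * 6)
        assert p > 0.5

    def test_below_min_n_untestable(self):
        assert np.isnan(signed_rank_test([1.0, 2.0, 3.0], [0.0] * 3))

    def test_all_zero_differences_untestable(self):
        assert np.isnan(signed_rank_test([1.0] * 6, [1.0] * 6))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_sign_flip_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        d = rng.normal(size=n)
        p = signed_rank_test(d, np.zeros(n), min_n=5)
        assert p == pytest.approx(signed_rank_p_enumeration(d), abs=1e-12)


class TestRankSumTest:
    def test_separated_samples_exact(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6], min_n=3) == pytest.approx(0.1)

    def test_identical_samples(self):
        assert rank_sum_test([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == 1.0

    def test_small_nation_untestable(self):
        assert np.isnan(rank_sum_test([1.0], [2.0, 3.0]))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_test([1.0, 2.0, 3.0, 4.0, 5.0], [])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_arrangement_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n, m = int(rng.integers(5, 9)), int(rng.integers(3, 9))
        x, y = rng.normal(size=n), rng.normal(size=m)
        p = rank_sum_test(x, y, min_n=3)
        assert p == pytest.approx(rank_sum_p_enumeration(x, y), abs=1e-12)


class TestNullModel:
    def _single_pa_dataset(self):
        # one PA covering exactly 40 of 400 cells (f = 0.1), coverage 1
        grid = square_grid(20, 20)
        pa = ProtectedArea(
            "BLOCK", "NP", {"AAA"}, 4000.0, geometry=box(0, 0, 80, 50)
        )
        rng = np.random.default_rng(5)
        cells = np.array(grid.land_cell_ids, dtype=object)
        occs = [
            SpeciesOccurrence(
                f"sp{i}",
                frozenset(cells[rng.choice(400, size=(i % 10) + 1, replace=False)]),
            )
            for i in range(20)
        ]
        return build_dataset(grid, occs, [pa])

    def test_mean_null_richness_matches_closed_form(self):
        # a PA holding fraction f of the land: under uniform redistribution
        # E[richness] ~ sum_i 1 - (1 - f)^freq_i (binomial limit of the
        # without-replacement draw)
        ds = self._single_pa_dataset()
        report = run_null_model_analysis(
            ds, metrics=["richness_rs"], n_sims=200, seed=123, min_n=99
        )
        sims = report.ensemble.values["richness_rs"][:, 0]
        f = 40 / 400
        freqs = np.array([occ.frequency for occ in ds.occurrences])
        closed = (1 - (1 - f) ** freqs).sum()
        se = sims.std(ddof=1) / np.sqrt(sims.size)
        assert abs(sims.mean() - closed) < 3 * se + 0.05

    def test_seed_determinism_and_frequency_conservation(self):
        ds = clone_nations_dataset()
        a = run_null_model_analysis(ds, metrics=["richness_rs"], n_sims=5, seed=9)
        b = run_null_model_analysis(ds, metrics=["richness_rs"], n_sims=9, seed=9)
        np.testing.assert_array_equal(
            a.ensemble.values["richness_rs"],
            b.ensemble.values["richness_rs"][:5],
        )
        pd.testing.assert_frame_equal(a.observed, b.observed)

    def test_zero_sims_rejected(self, tiny_dataset):
        with pytest.raises(DomainError):
            run_null_model_analysis(tiny_dataset, n_sims=0)

    def test_untested_nations_reported_missing(self):
        ds = clone_nations_dataset()
        report = run_null_model_analysis(
            ds, metrics=["richness_rs"], n_sims=10, seed=2, min_n=5
        )
        # 3 PAs per nation < min_n=5 -> every nation untested, never p=1
        assert report.table["p_vs_null"].isna().all()
        assert not report.table["sig_vs_null"].any()


class TestCrossValidation:
    def test_clone_nations_have_zero_sd(self):
        ds = clone_nations_dataset()
        report = cross_validate(ds, n_runs=12, n_keep=20, seed=3)
        assert report.sd.notna().to_numpy().all()
        assert float(report.sd.abs().max().max()) < 1e-6

    def test_each_run_retains_exactly_n_keep(self):
        ds = clone_nations_dataset()
        report = cross_validate(ds, n_runs=15, n_keep=20, seed=4)
        assert all(len(set(r)) == 20 for r in report.retained_nations)

    def test_single_run_sd_missing(self):
        ds = clone_nations_dataset()
        report = cross_validate(ds, n_runs=1, n_keep=20, seed=5)
        assert report.sd.isna().to_numpy().all()

    def test_keep_too_many_rejected(self):
        ds = clone_nations_dataset()
        with pytest.raises(DomainError):
            cross_validate(ds, n_runs=2, n_keep=25, seed=0)


class TestSpatialCorrelation:
    def test_identity_perfect_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        coords = rng.uniform(0, 100, size=(30, 2))
        res = spatial_correlation(x, x, coords)
        assert res.r == pytest.approx(1.0)
        assert res.p == 0.0

    def test_near_perfect_negative(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = -x + rng.normal(scale=1e-3, size=40)
        coords = rng.uniform(0, 100, size=(40, 2))
        res = spatial_correlation(x, y, coords)
        assert res.r == pytest.approx(-1.0, abs=1e-4)
        assert res.p < 0.01

    def test_zero_variance_rejected(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 10, size=(15, 2))
        with pytest.raises(DomainError):
            spatial_correlation(np.ones(15), rng.normal(size=15), coords)

    def test_white_noise_effective_n_close_to_n(self):
        # spatially independent variables: the correction should be nearly
        # a no-op (effective n within 15% of n, corrected p ~ raw p)
        rng = np.random.default_rng(3)
        n = 60
        ratios, p_gaps = [], []
        for _ in range(50):
            coords = rng.uniform(0, 100, size=(n, 2))
            res = spatial_correlation(
                rng.normal(size=n), rng.normal(size=n), coords
            )
            ratios.append(res.effective_n / n)
            p_gaps.append(abs(res.p - res.p_uncorrected))
        ratios = np.asarray(ratios)
        assert ratios.mean() > 0.85
        assert (ratios >= 0.85).mean() >= 0.9
        assert np.median(p_gaps) < 0.1
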