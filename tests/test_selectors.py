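import numpy as np
import pytest

from nirselect.dataset import SpectraSet
from nirselect.selectors import (
    BossConfig,
    GaConfig,
    SiplsConfig,
    SpaConfig,
    boss_select,
    ga_select,
    sipls_intervals,
    sipls_select,
    spa_select,
    SiPLSSelector,
)
from tests.conftest import make_planted


class TestSiplsIntervals:
    @pytest.mark.parametrize("p,k", [(397, 19), (400, 18), (60, 10), (100, 7)])
    def test_partition_near_equal_and_exhaustive(self, p, k):
        ivs = sipls_intervals(p, k)
        widths = [len(iv) for iv in ivs]
        assert max(widths) - min(widths) <= 1
        assert widths == sorted(widths, reverse=True)  # wider intervals first
        np.testing.assert_array_equal(np.concatenate(ivs), np.arange(p))

    def test_397_by_19_widths_and_union_size(self):
        ivs = sipls_intervals(397, 19)
        widths = {len(iv) for iv in ivs}
        assert widths == {20, 21}
        # any 4-interval union has 80..84 channels
        sizes = [sum(len(ivs[i]) for i in combo)
                 for combo in [(0, 1, 2, 3), (15, 16, 17, 18), (0, 6, 12, 18)]]
        assert all(80 <= s <= 84 for s in sizes)


class TestSipls:
    def test_planted_interval_always_wins(self):
        for s in range(10):
            sp = make_planted(s, n=80, p=60, informative=(24, 25, 26, 27), noise=0.2)
            res = sipls_select(sp, SiplsConfig(n_intervals=10, n_combine=2, seed=s))
            assert 4 in res.meta["winning_intervals"]

    def test_combine_all_returns_every_channel(self):
        sp = make_planted(0, n=40, p=30)
        res = sipls_select(sp, SiplsConfig(n_intervals=5, n_combine=5, seed=0))
        assert res.n_selected == 30

    def test_combination_explosion_guard(self):
        sp = make_planted(0, n=40, p=30)
        with pytest.raises(ValueError, match="reduce n_combine"):
            sipls_select(sp, SiplsConfig(n_intervals=30, n_combine=15, seed=0))

    def test_estimator_wrapper(self):
        sp = make_planted(1, n=60, p=40, informative=(12, 13), noise=0.2)
        est = SiPLSSelector(n_intervals=8, n_combine=2, seed=0).fit(sp.X, sp.y)
        assert est.get_support().sum() == est.selection_result_.n_selected


class TestSpa:
    def test_never_selects_both_duplicated_channels(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 8))
        X[:, 5] = X[:, 2]  # exact duplicate
        sp = SpectraSet(X, np.arange(8.0), y=X[:, 1] + 0.1 * rng.normal(size=40))
        res = spa_select(sp, SpaConfig(min_vars=2, max_vars=6, seed=0))
        sel = set(res.selected_indices.tolist())
        assert not {2, 5} <= sel

    def test_single_variable_base_case_best_channel(self):
        sp = make_planted(2, n=60, p=10, informative=(4,), noise=0.1)
        res = spa_select(sp, SpaConfig(min_vars=1, max_vars=1, seed=0))
        np.testing.assert_array_equal(res.selected_indices, [4])

    def test_orthogonal_design_reaches_all_columns(self):
        # orthonormal columns: projections never vanish, chain can take all 5
        q, _ = np.linalg.qr(np.random.default_rng(3).normal(size=(30, 5)))
        y = q @ np.array([3.0, 2.5, 2.0, 1.5, 1.0])
        sp = SpectraSet(q, np.arange(5.0), y=y)
        res = spa_select(sp, SpaConfig(min_vars=5, max_vars=5, seed=0))
        assert res.n_selected == 5


class TestGa:
    def test_same_seed_identical_result(self):
        sp = make_planted(0, n=60, p=30, informative=(5, 20), noise=0.2)
        cfg = GaConfig(n_generations=10, cv_repeats=3, seed=4)
        r1, r2 = ga_select(sp, cfg), ga_select(sp, cfg)
        np.testing.assert_array_equal(r1.selected_indices, r2.selected_indices)
        assert r1.rmse_trajectory == r2.rmse_trajectory

    def test_informative_chromosome_beats_noise_chromosome(self):
        from nirselect.selectors import _SplitScorer
        sp = make_planted(1, n=80, p=40, informative=(3, 17, 33), noise=0.2)
        scorer = _SplitScorer(sp.X, sp.y, 10, 5, np.random.default_rng(0))
        informative = scorer.rmse(np.array([3, 17, 33]))
        noise_only = scorer.rmse(np.array([0, 1, 2, 4, 5, 6]))
        assert informative < noise_only

    def test_recovers_planted_pair(self):
        wins = 0
        for s in range(10):
            sp = make_planted(s, n=80, p=50, informative=(7, 33), noise=0.3)
            res = ga_select(sp, GaConfig(n_generations=50, cv_repeats=3, seed=s))
            wins += {7, 33} <= set(res.selected_indices.tolist())
        assert wins >= 8

    def test_tiny_population_rejected(self):
        with pytest.raises(ValueError):
            GaConfig(population_size=2)


class TestBoss:
    def test_recovers_planted_triple(self):
        wins = 0
        for s in range(10):
            sp = make_planted(s, n=80, p=60, informative=(10, 25, 40),
                              coefs=[1.0, 0.8, 1.2], noise=0.3)
            res = boss_select(sp, BossConfig(n_submodels=300, seed=s))
            wins += {10, 25, 40} <= set(res.selected_indices.tolist())
        assert wins >= 8

    def test_weights_normalized_every_round(self):
        sp = make_planted(0, n=60, p=30, informative=(5, 20), noise=0.2)
        res = boss_select(sp, BossConfig(n_submodels=100, seed=0))
        for rec in res.iteration_log:
            assert abs(rec["weight_sum"] - 1.0) < 1e-12

    def test_same_seed_identical_result(self):
        sp = make_planted(2, n=60, p=30, informative=(5, 20), noise=0.2)
        cfg = BossConfig(n_submodels=100, seed=7)
        r1, r2 = boss_select(sp, cfg), boss_select(sp, cfg)
        np.testing.assert_array_equal(r1.selected_indices, r2.selected_indices)


def test_all_selectors_return_subset_of_input_channels():
    sp = make_planted(0, n=60, p=30, informative=(5, 20), noise=0.2)
    results = [
        sipls_select(sp, SiplsConfig(n_intervals=6, n_combine=2, seed=0)),
        spa_select(sp, SpaConfig(min_vars=2, max_vars=5, seed=0)),
        ga_select(sp, GaConfig(n_generations=5, cv_repeats=3, seed=0)),
        boss_select(sp, BossConfig(n_submodels=50, seed=0)),
    ]
    for res in results:
        assert np.all((res.selected_indices >= 0) & (res.selected_indices < 30))
        assert len(set(res.selected_indices.tolist())) == res.n_selected
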