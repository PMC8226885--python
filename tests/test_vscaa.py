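import math

import numpy as np
import pytest

from nirselect.dataset import SpectraSet
from nirselect.stability import StabilityConfig
from nirselect.vscaa import (
    VscaaConfig,
    VSCAASelector,
    chain_select,
    decay_schedule,
    frequency_profile,
    vscaa_select,
    wbs_partition,
)
from tests.conftest import make_planted


class TestWbsPartition:
    def test_equal_weights_mean_fraction_632(self):
        # E[distinct fraction] = 1 - (1 - 1/p)^p; check the simulation mean.
        p = 1000
        expected = 1 - (1 - 1 / p) ** p
        fractions = [
            len(wbs_partition(np.ones(p), seed=s)[0]) / p for s in range(300)
        ]
        assert abs(np.mean(fractions) - expected) < 0.01

    def test_dominant_weight_always_useful(self):
        w = np.full(100, 1e-3)
        w[42] = 999.0
        for s in range(50):
            useful, _ = wbs_partition(w, seed=s)
            assert 42 in useful

    def test_two_channel_binomial_oracle(self):
        # p=2 with weights (1, eps): P(channel 0 useful) = 1-(eps/(1+eps))^2 -> 1.
        eps = 1e-6
        hits = sum(
            0 in wbs_partition(np.array([1.0, eps]), seed=s)[0] for s in range(200)
        )
        assert hits == 200

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            wbs_partition(np.zeros(5), seed=0)

    def test_partition_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.1, 1, 50)
        useful, useless = wbs_partition(w, seed=1)
        merged = np.sort(np.concatenate([useful, useless]))
        np.testing.assert_array_equal(merged, np.arange(50))


class TestDecaySchedule:
    def test_cars_standard_constants_p397_n20(self):
        # closed form: alpha = (p/2)^{1/(N-1)}, k = ln(p/2)/(N-1)
        sch = decay_schedule(397, 20)
        assert abs(sch.alpha - (397 / 2) ** (1 / 19)) < 1e-12
        assert abs(sch.k - math.log(397 / 2) / 19) < 1e-12
        assert abs(sch.r[0] - 1.0) < 1e-12
        assert sch.counts[0] == 397
        assert sch.counts[-1] == 2

    def test_smallest_legal_schedule(self):
        sch = decay_schedule(4, 2)
        assert abs(sch.alpha - 2.0) < 1e-12
        assert abs(sch.k - math.log(2)) < 1e-12
        np.testing.assert_allclose(sch.r, [1.0, 0.5])
        np.testing.assert_array_equal(sch.counts, [4, 2])

    def test_as_printed_barely_eliminates(self):
        sch = decay_schedule(397, 20, "as_printed")
        assert abs(sch.k - math.log((397 / 2) ** (1 / 19)) / 19) < 1e-12
        assert sch.r[-1] > 0.98  # near-zero elimination
        # whereas the standard convention ends at two variables
        assert decay_schedule(397, 20).counts[-1] == 2

    def test_counts_non_increasing_and_bounded(self):
        for p, N in [(50, 10), (397, 20), (400, 50)]:
            sch = decay_schedule(p, N)
            assert np.all(np.diff(sch.counts) <= 0)
            assert sch.counts[0] <= p and sch.counts[-1] >= 2

    def test_too_few_variables_rejected(self):
        with pytest.raises(ValueError):
            decay_schedule(3, 5)


class TestFrequencyProfile:
    def test_null_aggregate_roughly_uniform(self):
        # Conditional on one dataset the best submodels concentrate on
        # spuriously y-correlated channels, so uniformity is checked on
        # the aggregate over independent datasets.
        agg = np.zeros(40)
        for s in range(20):
            rng = np.random.default_rng(s)
            sp = SpectraSet(
                rng.normal(size=(50, 40)), np.arange(40.0), y=rng.normal(size=50)
            )
            agg += frequency_profile(sp, space_size=10, n_spaces=500, seed=s).f
        dev = np.abs(agg - agg.mean()) / agg.mean()
        assert dev.max() < 0.4

    def test_planted_channels_exceed_95th_percentile(self):
        wins = 0
        for s in range(20):
            sp = make_planted(s, n=100, p=100, informative=(10, 20), noise=0.3)
            f = frequency_profile(sp, space_size=25, n_spaces=500, seed=s).f
            rest = np.delete(f, [10, 20])
            thr = np.percentile(rest, 95)
            wins += (f[10] > thr) and (f[20] > thr)
        assert wins >= 18

    def test_retention_one_counts_all_spaces(self):
        sp = make_planted(0, n=30, p=20)
        fp = frequency_profile(sp, space_size=5, n_spaces=100, model_retention=1.0, seed=0)
        assert fp.models_kept == 100
        assert fp.f.sum() == 100 * 5

    def test_space_size_bounds(self):
        sp = make_planted(0, n=30, p=20)
        with pytest.raises(ValueError):
            frequency_profile(sp, space_size=21, n_spaces=50, seed=0)


def small_cfg(seed):
    return VscaaConfig(
        n_loops=10,
        variable_spaces=50,
        stability_config=StabilityConfig(n_sample_spaces=20, seed=seed),
        seed=seed,
    )


class TestVscaaSelect:

    def test_monotone_shrinkage_and_floor(self):
        for seed in range(3):
            s = make_planted(seed, n=60, p=30, informative=(5, 15), noise=0.2)
            res = vscaa_select(s, small_cfg(seed))
            retained = [rec["retained"] for rec in res.iteration_log]
            assert all(a >= b for a, b in zip(retained, retained[1:]))
            assert retained[-1] >= 2
            # survivor sets nest: eliminated sets are disjoint from later survivors
            sch = res.meta["schedule"]["counts"]
            assert all(r <= c for r, c in zip(retained, sch))

    def test_returned_rmse_is_trajectory_minimum(self):
        s = make_planted(3, n=60, p=30, informative=(5, 15), noise=0.2)
        res = vscaa_select(s, small_cfg(3))
        assert res.meta["best_rmse"] == min(res.rmse_trajectory)
        best_it = res.meta["best_iteration"]
        assert res.rmse_trajectory[best_it - 1] == res.meta["best_rmse"]
        assert res.n_selected == res.iteration_log[best_it - 1]["retained"]

    def test_same_seed_same_result(self):
        s = make_planted(4, n=60, p=30)
        r1 = vscaa_select(s, small_cfg(9))
        r2 = vscaa_select(s, small_cfg(9))
        np.testing.assert_array_equal(r1.selected_indices, r2.selected_indices)
        assert r1.rmse_trajectory == r2.rmse_trajectory

    def test_planted_channels_survive_small_case(self):
        hits = 0
        for seed in range(5):
            s = make_planted(seed, n=80, p=30, informative=(5, 15), noise=0.15)
            res = vscaa_select(s, small_cfg(seed))
            hits += {5, 15} <= set(res.selected_indices.tolist())
        assert hits >= 4

    def test_degenerate_y_rejected(self):
        s = SpectraSet(np.random.default_rng(0).normal(size=(20, 10)),
                       np.arange(10.0), y=np.ones(20))
        with pytest.raises(ValueError, match="degenerate y"):
            vscaa_select(s, VscaaConfig())

    def test_selector_estimator_support_mask(self):
        s = make_planted(0, n=60, p=20, informative=(3, 11), noise=0.2)
        est = VSCAASelector(n_loops=5, variable_spaces=20, n_sample_spaces=10, seed=0)
        est.fit(s.X, s.y)
        mask = est.get_support()
        assert mask.sum() == est.selection_result_.n_selected
        assert est.transform(s.X).shape == (60, mask.sum())


class TestChainSelect:
    def test_identity_chain_returns_all_channels(self):
        s = make_planted(0, n=30, p=15)
        def identity(sp):
            from nirselect.pipeline import make_selector
            return make_selector("identity")(sp)
        res = chain_select(s, [("identity", identity)])
        assert res.n_selected == 15

    def test_empty_chain_is_full_set(self):
        s = make_planted(0, n=30, p=15)
        res = chain_select(s, [])
        assert res.n_selected == 15
        assert res.method_name == "identity"

    def test_composition_maps_to_original_axis(self):
        s = make_planted(1, n=60, p=40, informative=(8, 30), noise=0.2)

        def take_even(sp):
            from nirselect.dataset import SelectionResult
            idx = np.arange(0, sp.n_channels, 2)
            return SelectionResult(idx, sp.wavelengths[idx], "even")

        def take_first_half(sp):
            from nirselect.dataset import SelectionResult
            idx = np.arange(sp.n_channels // 2)
            return SelectionResult(idx, sp.wavelengths[idx], "half")

        res = chain_select(s, [("even", take_even), ("half", take_first_half)])
        np.testing.assert_array_equal(res.selected_indices, np.arange(0, 20, 2))
        assert res.method_name == "even-half"

    def test_stage_returning_too_few_identified(self):
        s = make_planted(0, n=30, p=15)

        def bad(sp):
            from nirselect.dataset import SelectionResult
            return SelectionResult(np.array([3]), sp.wavelengths[[3]], "bad")

        with pytest.raises(ValueError, match="stage 0"):
            chain_select(s, [("bad", bad)])
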