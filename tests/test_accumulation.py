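import itertools
import math

import numpy as np
import pytest

from hilltac import (
    CommunityTable,
    default_depth_grid,
    depth_analysis,
    expected_rarefied_richness,
    expected_richness_tac,
    hill_number,
    pool_samples,
    smoothed_tac,
    stability_score,
    subsample_reads,
)


def brute_force_tac(table, a):
    """Average diversity over every sample ordering, enumerated directly."""
    n = table.n_samples
    sums = np.zeros(n)
    perms = list(itertools.permutations(range(n)))
    for perm in perms:
        for k in range(1, n + 1):
            pooled = table.counts[:, list(perm[:k])].sum(axis=1)
            sums[k - 1] += hill_number(pooled, a)
    return sums / len(perms)


class TestSmoothedTac:
    def test_exhaustive_matches_enumeration_oracle(self, three_sample_table):
        curve = smoothed_tac(three_sample_table, a=0, exhaustive=True)
        expected = brute_force_tac(three_sample_table, a=0)
        np.testing.assert_allclose(curve.mean, expected, rtol=1e-12)
        assert curve.n_perm == math.factorial(3)

    def test_identical_samples_give_flat_curve(self):
        col = np.array([10, 5, 2, 1])
        table = CommunityTable(
            ("a", "b", "c", "d"),
            ("s1", "s2", "s3"),
            np.column_stack([col, col, col]),
        )
        curve = smoothed_tac(table, a=2, n_perm=5, seed=1)
        np.testing.assert_allclose(curve.mean, hill_number(col, 2), rtol=1e-12)

    def test_richness_curve_monotone_with_exact_final_point(self, three_sample_table):
        curve = smoothed_tac(three_sample_table, a=0, n_perm=20, seed=3)
        assert np.all(np.diff(curve.mean) >= 0)
        pooled_s = (pool_samples(three_sample_table) > 0).sum()
        assert curve.mean[-1] == pooled_s
        assert np.all(curve.mean <= pooled_s)

    def test_monte_carlo_matches_analytic_richness_expectation(self, rng):
        counts = rng.integers(0, 4, size=(120, 10))
        counts[0, 0] += 1
        table = CommunityTable(
            tuple(f"t{i}" for i in range(120)),
            tuple(f"s{j}" for j in range(10)),
            counts,
        )
        curve = smoothed_tac(table, a=0, n_perm=300, seed=5)
        expected = expected_richness_tac(table)
        se = curve.sd / np.sqrt(curve.n_perm)
        assert np.all(np.abs(curve.mean - expected) <= 3 * se + 1e-9)

    def test_same_seed_is_bit_identical(self, three_sample_table):
        a = smoothed_tac(three_sample_table, a=1, n_perm=30, seed=9)
        b = smoothed_tac(three_sample_table, a=1, n_perm=30, seed=9)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.sd, b.sd)

    def test_single_sample_table_rejected(self):
        table = CommunityTable(("a", "b"), ("only",), np.array([[3], [1]]))
        with pytest.raises(ValueError, match="depth_analysis"):
            smoothed_tac(table, a=0)

    def test_zero_read_sample_rejected(self):
        table = CommunityTable(
            ("a", "b"), ("x", "y"), np.array([[3, 0], [1, 0]])
        )
        with pytest.raises(ValueError, match="zero reads"):
            smoothed_tac(table, a=0)


class TestSubsampleReads:
    def test_full_depth_returns_input(self):
        v = np.array([5, 0, 3, 2])
        np.testing.assert_array_equal(subsample_reads(v, 10, seed=0), v)

    def test_depth_one_is_single_read(self):
        out = subsample_reads([4, 4, 4], 1, seed=2)
        assert out.sum() == 1
        assert (out > 0).sum() == 1

    def test_sum_is_exact_and_dominated(self, rng):
        v = rng.integers(0, 50, size=25)
        v[0] += 1
        for depth in (1, 7, int(v.sum()) // 2):
            sub = subsample_reads(v, depth, seed=rng)
            assert sub.sum() == depth
            assert np.all(sub <= v)

    def test_excess_depth_states_both_numbers(self):
        with pytest.raises(ValueError, match="15.*10"):
            subsample_reads([5, 5], 15)

    def test_multinomial_method_allows_oversampling(self):
        out = subsample_reads([5, 5], 30, seed=1, method="multinomial")
        assert out.sum() == 30

    def test_mean_richness_matches_hypergeometric_expectation(self, rng):
        v = rng.integers(0, 12, size=40)
        v[0] += 1
        depth = int(v.sum()) // 3
        draws = np.array(
            [(subsample_reads(v, depth, seed=rng) > 0).sum() for _ in range(400)]
        )
        expected = expected_rarefied_richness(v, depth)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) <= 3 * se + 1e-9

    def test_same_seed_same_draw(self):
        v = [9, 4, 2, 1]
        a = subsample_reads(v, 8, seed=42)
        b = subsample_reads(v, 8, seed=42)
        np.testing.assert_array_equal(a, b)


class TestStabilityScore:
    def test_constant_curve_stable_at_first_step(self):
        reached, at_step = stability_score([1, 2, 3, 4, 5], [7, 7, 7, 7, 7])
        assert reached and at_step == 1

    def test_steep_linear_curve_never_stable(self):
        steps = np.arange(1, 11)
        reached, at_step = stability_score(steps, 10.0 * steps, tol=0.02)
        assert not reached and at_step is None

    def test_saturating_curve_matches_analytic_criterion(self):
        # C(x) = S (1 - exp(-x / tau)); evaluate the declared criterion on
        # the closed form directly and compare the declared step.
        s_max, tau = 100.0, 400.0
        steps = np.linspace(50, 4000, 40)
        mean = s_max * (1 - np.exp(-steps / tau))
        window_frac, tol = 0.1, 0.02
        window = window_frac * (steps[-1] - steps[0])

        def analytic_first_stable():
            for i, x in enumerate(steps[:-1]):
                ahead = np.nonzero(steps >= x + window)[0]
                ahead = ahead[ahead > i]
                if ahead.size == 0:
                    return None
                x_end = steps[ahead[0]]
                c_x = s_max * (1 - math.exp(-x / tau))
                c_end = s_max * (1 - math.exp(-x_end / tau))
                if (c_end - c_x) / c_x <= tol:  # curve is increasing
                    return steps[i]
            return None

        reached, at_step = stability_score(
            steps, mean, window_frac=window_frac, tol=tol
        )
        expected = analytic_first_stable()
        assert reached and at_step == int(round(expected))
        # sanity: saturation point is interior, not the first or last step
        assert steps[0] < expected < steps[-1]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            stability_score([1, 2, 3], [1, 2])

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValueError, match="3"):
            stability_score([1, 2], [1, 1])


class TestDepthAnalysis:
    def test_full_depth_replicates_equal_full_data_value(self):
        v = np.array([50, 30, 10, 5, 3, 1, 1])
        n = int(v.sum())
        res = depth_analysis(v, depths=[n // 4, n // 2, n], reps=4, seed=0)
        for a in res.orders:
            np.testing.assert_allclose(
                res.values[a][:, -1], hill_number(v, a), rtol=1e-12
            )

    def test_uniform_community_stable_immediately(self):
        v = np.full(10, 600)  # 10 equally common taxa, no rare tail
        res = depth_analysis(
            v, depths=[500, 1500, 3000, 6000], reps=5, seed=1
        )
        for a in res.orders:
            assert res.stability_depth[a] == 500

    def test_heavy_tail_orders_stabilize_in_sequence(self, rng):
        # log-normal community with a strong rare tail: higher orders
        # stabilize no later than lower ones
        from hilltac import CommunitySpec, make_community, sample_reads

        spec = CommunitySpec(S=2000, tad="lognormal", sigma=2.0, seed=5)
        v = sample_reads(make_community(spec), 120000, seed=6)
        res = depth_analysis(v, reps=6, seed=7)
        inf = float("inf")
        stab = {a: res.stability_depth[a] if res.stability_depth[a] is not None
                else inf for a in (0.0, 1.0, 2.0)}
        assert stab[2.0] <= stab[1.0] <= stab[0.0]

    def test_every_replicate_sums_checked_by_depth_grid(self):
        v = np.array([40, 25, 10, 3, 1, 1])
        with pytest.raises(ValueError, match="ascending"):
            depth_analysis(v, depths=[30, 20, 10], reps=2)

    def test_default_grid_spans_sixteenfold(self):
        grid = default_depth_grid(400000)
        assert grid[0] == 25000 and grid[-1] == 400000
        assert grid.size == 8
        ratios = grid[1:] / grid[:-1]
        assert np.allclose(ratios, ratios[0], rtol=0.01)
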