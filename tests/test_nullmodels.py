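import itertools
import math

import numpy as np
import pytest

from catchassoc.nullmodels import (
    _companion_stat, _sample_occupied_counts, _surjections,
    aggregation_test, assortment_test, companion_preference_test)


def mc_band(p_exact, n_reps):
    """Three Monte-Carlo standard errors plus the add-one offset."""
    return 3 * math.sqrt(p_exact * (1 - p_exact) / n_reps) + 2 / (n_reps + 1)


class TestAggregationOracle:
    """Exhaustive enumeration of all E^N uniform assignments."""

    @staticmethod
    def exact_p(sizes, statistic):
        sizes = np.asarray(sizes)
        n, e = sizes.sum(), len(sizes)

        def stat(counts):
            counts = np.asarray(counts)
            ne = (counts > 0).sum()
            if statistic == "prevalence_multi":
                return (counts > 1).sum() / ne
            return counts.sum() / ne

        obs = stat(sizes)
        hits = total = 0
        for assign in itertools.product(range(e), repeat=n):
            counts = np.bincount(assign, minlength=e)
            total += 1
            hits += stat(counts) >= obs - 1e-12
        return hits / total

    def test_all_in_one_event_mean_size(self):
        # N=4, E=2, observed {4,0}: exactly 2 of 16 assignments put
        # everyone together, so p -> 0.125 under the mean-size statistic
        exact = self.exact_p([4, 0], "mean_size_nonempty")
        assert exact == pytest.approx(2 / 16)
        res = aggregation_test([4, 0], statistic="mean_size_nonempty",
                               n_reps=4000, seed=0)
        assert abs(res.p_value - exact) <= mc_band(exact, 4000)

    def test_all_in_one_event_prevalence_ties_with_even_split(self):
        # under the prevalence statistic the {2,2} split also scores 1.0,
        # so the exact tail is 8/16, not 2/16
        exact = self.exact_p([4, 0], "prevalence_multi")
        assert exact == pytest.approx(8 / 16)
        res = aggregation_test([4, 0], statistic="prevalence_multi",
                               n_reps=4000, seed=1)
        assert abs(res.p_value - exact) <= mc_band(exact, 4000)

    def test_everyone_alone_is_unremarkable(self):
        res = aggregation_test([1] * 6, n_reps=500, seed=2)
        assert res.observed == 0.0
        assert res.p_value > 0.5

    def test_input_validation(self):
        with pytest.raises(ValueError):
            aggregation_test([], n_reps=200)
        with pytest.warns(UserWarning):
            aggregation_test([2, 1], n_reps=50, seed=0)

    def test_reproducible_for_fixed_seed(self):
        a = aggregation_test([3, 1, 1], n_reps=500, seed=9)
        b = aggregation_test([3, 1, 1], n_reps=500, seed=9)
        assert a.to_dict() == b.to_dict()


class TestOccupancyConditionedNull:
    def test_surjection_counts_match_closed_form(self):
        # surjections(n, 2) = 2^n - 2 for n >= 1
        for n in range(2, 8):
            assert _surjections(n, 2) == 2 ** n - 2
        assert _surjections(3, 3) == math.factorial(3)

    def test_sampler_matches_enumerated_conditional(self):
        # N=5 into E=3 occupied boxes: P(first box = k) by enumeration
        hits = {}
        total = 0
        for assign in itertools.product(range(3), repeat=5):
            counts = np.bincount(assign, minlength=3)
            if (counts > 0).all():
                total += 1
                hits[counts[0]] = hits.get(counts[0], 0) + 1
        exact = {k: v / total for k, v in hits.items()}
        draws = _sample_occupied_counts(5, 3, 20000,
                                        np.random.default_rng(3))
        assert (draws > 0).all() and (draws.sum(axis=1) == 5).all()
        for k, p in exact.items():
            emp = np.mean(draws[:, 0] == k)
            assert abs(emp - p) <= 3 * math.sqrt(p * (1 - p) / 20000)

    def test_conditioned_test_rejects_zero_sizes(self):
        with pytest.raises(ValueError):
            aggregation_test([2, 0], condition_nonempty=True, n_reps=200)


class TestAssortmentOracle:
    def test_two_single_sex_events_exact_third(self):
        # pool MMFF over two events of two: 8 of 24 orderings leave both
        # events single-sex, so exact p = 1/3
        res = assortment_test([["male", "male"], ["female", "female"]],
                              trait="sex", n_reps=6000, seed=0)
        assert res.observed == 1.0
        assert abs(res.p_value - 1 / 3) <= mc_band(1 / 3, 6000)

    def test_mean_imbalance_statistic_same_exact_tail(self):
        # on the {MM},{FF} toy the imbalance statistic orders assignments
        # identically (1.0 iff both events single-sex), so the exact tail
        # is again 1/3
        res = assortment_test([["male", "male"], ["female", "female"]],
                              trait="sex", statistic="mean_sex_imbalance",
                              n_reps=6000, seed=1)
        assert res.observed == 1.0
        assert abs(res.p_value - 1 / 3) <= mc_band(1 / 3, 6000)

    def test_constant_trait_is_degenerate(self):
        with pytest.warns(UserWarning):
            res = assortment_test([["male", "male"], ["male", "male"]],
                                  trait="sex", n_reps=200, seed=0)
        assert res.degenerate and res.p_value == 1.0

    def test_fork_length_tail_matches_full_enumeration(self):
        # tight events out of a wide pool; exact tail from all 6! orderings
        groups = [[500.0, 502.0], [700.0, 703.0], [400.0, 401.0]]
        pool = [v for g in groups for v in g]
        obs = np.mean([max(g) - min(g) for g in groups])
        tail = []
        for perm in itertools.permutations(pool):
            ranges = [max(perm[i:i + 2]) - min(perm[i:i + 2])
                      for i in (0, 2, 4)]
            tail.append(np.mean(ranges) <= obs + 1e-9)
        exact = float(np.mean(tail))
        res = assortment_test(groups, trait="fork_length",
                              n_reps=2000, seed=4)
        assert res.direction == "less"
        assert res.observed == pytest.approx(obs)
        assert res.observed < res.null_mean
        assert abs(res.p_value - exact) <= mc_band(exact, 2000)

    def test_stratified_permutation_stays_within_strata(self):
        # one all-male stratum and one all-female stratum: within-stratum
        # relabelling can never change the statistic -> p = 1
        groups = [["male", "male"], ["male", "male"],
                  ["female", "female"], ["female", "female"]]
        res = assortment_test(groups, trait="sex", strata=[0, 0, 1, 1],
                              n_reps=300, seed=0)
        assert res.p_value == 1.0
        # pooled permutation sees the same pattern as extreme
        pooled = assortment_test(groups, trait="sex", n_reps=2000, seed=0)
        assert pooled.p_value < 0.1

    def test_strata_length_validated(self):
        with pytest.raises(ValueError):
            assortment_test([["male", "female"]], strata=[0, 1], n_reps=200)


def enumerate_fixed_margin_matrices(row_sums, col_sums):
    """All 0/1 matrices with the given margins, by brute force."""
    n_rows, n_cols = len(row_sums), len(col_sums)
    mats = []
    row_choices = [list(itertools.combinations(range(n_cols), r))
                   for r in row_sums]
    for rows in itertools.product(*row_choices):
        mat = np.zeros((n_rows, n_cols), dtype=int)
        for i, cols in enumerate(rows):
            mat[i, list(cols)] = 1
        if np.array_equal(mat.sum(axis=0), col_sums):
            mats.append(mat)
    return mats


class TestCompanionOracle:
    observed = np.array([
        [1, 1, 0, 0],
        [1, 1, 0, 0],
        [0, 0, 1, 1],
        [0, 0, 1, 1]])

    @pytest.mark.parametrize("statistic", ["repeat_pairs", "repeat_dyads"])
    def test_chain_p_matches_exhaustive_enumeration(self, statistic):
        mats = enumerate_fixed_margin_matrices([2, 2, 2, 2], [2, 2, 2, 2])
        assert len(mats) == 90
        obs = _companion_stat(self.observed, statistic)
        tail = [_companion_stat(m, statistic) >= obs for m in mats]
        exact = float(np.mean(tail))
        res = companion_preference_test(
            self.observed, n_reps=1500, statistic=statistic, seed=0)
        # thinned swap-chain samples remain weakly correlated, so allow a
        # generous Monte-Carlo band around the exact tail probability
        assert abs(res.p_value - exact) <= 2 * mc_band(exact, 1500)

    def test_margins_preserved_throughout_chain(self):
        companion_preference_test(self.observed, n_reps=50, seed=1,
                                  check_margins=True)

    def test_two_by_two_full_dyad_is_degenerate(self):
        both = np.ones((2, 2), dtype=int)
        with pytest.warns(UserWarning):
            res = companion_preference_test(both, n_reps=100, seed=0)
        assert res.degenerate and res.p_value == 1.0
        assert "no checkerboard" in res.note

    def test_empty_incidence_is_degenerate(self):
        res = companion_preference_test(np.zeros((3, 0)), n_reps=50, seed=0)
        assert res.degenerate

    def test_block_list_statistic_sums_over_blocks(self):
        one = self.observed
        res_single = companion_preference_test(one, n_reps=100, seed=3)
        res_blocks = companion_preference_test([one, one], n_reps=100, seed=3)
        assert res_blocks.observed == 2 * res_single.observed

    def test_reproducible_for_fixed_seed(self):
        a = companion_preference_test(self.observed, n_reps=200, seed=11)
        b = companion_preference_test(self.observed, n_reps=200, seed=11)
        assert a.to_dict() == b.to_dict()
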