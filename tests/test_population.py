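"""Permutation correlations, chi-square, group contrasts, sorting, averaging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pptn_tonic.population import (abs_modulation, chi_square_2x2,
                                   group_rate_comparison, population_average,
                                   sort_by_onset, spearman_perm,
                                   summarize_population)
from pptn_tonic.roc import NormalizedActivityTrace


def pearson_chi2_by_hand(table):
    """Closed-form Pearson statistic (the independent oracle)."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = t[i].sum() * t[:, j].sum() / n
            stat += (t[i, j] - e) ** 2 / e
    return stat


class TestSpearmanPerm:
    def test_perfect_rank_agreement_hits_p_floor(self):
        x = np.array([3.0, 1.0, 7.0, 4.0, 9.0, 2.0,
                      11.0, 5.0, 8.0, 6.0, 10.0, 12.0])
        res = spearman_perm(x, 2 * x + 1, n_shuffles=999, seed=0)
        assert res.rho == pytest.approx(1.0)
        assert res.p_perm == pytest.approx(1.0 / 1000)

    def test_rho_matches_scipy_with_ties(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 6, 60).astype(float)  # many ties
        y = x + rng.normal(0, 2, 60)
        res = spearman_perm(x, y, n_shuffles=200, seed=1)
        assert res.rho == pytest.approx(stats.spearmanr(x, y).statistic,
                                        abs=1e-12)

    def test_rho_symmetric_in_arguments(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=40), rng.normal(size=40)
        assert spearman_perm(x, y, 100, seed=2).rho == pytest.approx(
            spearman_perm(y, x, 100, seed=3).rho)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=30), rng.normal(size=30)
        a = spearman_perm(x, y, 2000, seed=11)
        b = spearman_perm(x, y, 2000, seed=11)
        assert a == b

    def test_constant_vector_flagged(self):
        res = spearman_perm(np.ones(10), np.arange(10.0), 100, seed=0)
        assert res.rho is None and res.p_perm is None

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_perm([1.0, 2.0], [1.0, 2.0])

    def test_moderate_dependence_significant_at_reported_sample_size(self):
        """Rank correlation ~0.4 at n = 376 neurons is decisively detected."""
        rng = np.random.default_rng(8)
        z = rng.normal(size=376)
        x = z + rng.normal(0, 1.5, 376)
        y = z + rng.normal(0, 1.5, 376)  # population rho ~ 0.31
        res = spearman_perm(x, y, n_shuffles=5000, seed=9)
        assert res.rho > 0
        assert res.p_perm < 0.05


class TestAbsModulation:
    @pytest.mark.parametrize("roc,expected", [(0.5, 0.0), (0.75, 0.25),
                                              (0.1, 0.4), (1.0, 0.5)])
    def test_distance_from_indifference(self, roc, expected):
        assert abs_modulation(roc) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            abs_modulation(1.2)


class TestChiSquare:
    def test_reported_pre_onset_contrast_is_significant(self):
        # 284/372 excitatory vs 74/114 suppressive neurons with early onsets
        stat, p = chi_square_2x2([[284, 88], [74, 40]])
        assert p < 0.05

    def test_proportional_table_is_exactly_null(self):
        stat, p = chi_square_2x2([[10, 10], [20, 20]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_association(self):
        stat, _ = chi_square_2x2([[50, 0], [0, 50]])
        assert stat == pytest.approx(100.0)

    def test_matches_hand_formula_on_random_small_tables(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            t = rng.integers(1, 21, size=(2, 2))
            stat, _ = chi_square_2x2(t)
            assert stat == pytest.approx(pearson_chi2_by_hand(t))

    def test_degenerate_margin_flagged(self):
        assert chi_square_2x2([[0, 0], [5, 3]]) == (None, None)
        with pytest.raises(ValueError):
            chi_square_2x2([[1, 2, 3], [4, 5, 6]])


class TestGroupRateComparison:
    def _rates(self, rng, medians, n=200):
        names = ["excitatory_pre", "excitatory_post",
                 "suppressive_pre", "suppressive_post"]
        return {nm: np.exp(np.log(m) + rng.normal(0, 0.4, n))
                for nm, m in zip(names, medians)}

    def test_distinct_baselines_detected(self):
        # excitatory baseline median 9.6 vs suppressive 16.2 spikes/s
        rng = np.random.default_rng(11)
        rates = self._rates(rng, (9.6, 19.2, 16.2, 2.0))
        res = group_rate_comparison(rates)
        assert len(res) == 6
        pre = next(r for r in res if (r.group_a, r.group_b)
                   == ("excitatory_pre", "suppressive_pre"))
        assert pre.significant
        assert pre.p < 0.05 / 6

    def test_identical_samples_all_null(self):
        x = np.arange(1.0, 21.0)
        res = group_rate_comparison({k: x for k in "abcd"})
        assert all(r.p == pytest.approx(1.0) for r in res)
        assert not any(r.significant for r in res)

    def test_family_error_calibrated_under_global_null(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(400):
            rates = {k: rng.normal(10, 2, 30) for k in "abcd"}
            hits += any(r.significant for r in group_rate_comparison(rates))
        # expected family-wise rate ~5% with Bonferroni 0.05/6
        assert hits / 400 < 0.10

    def test_empty_group_omits_its_comparisons(self):
        rates = {"a": np.arange(5.0), "b": np.empty(0),
                 "c": np.arange(5.0), "d": np.arange(5.0)}
        res = group_rate_comparison(rates)
        assert len(res) == 3
        assert not any("b" in (r.group_a, r.group_b) for r in res)


class TestSortingAndAveraging:
    def test_onset_order_example(self):
        assert sort_by_onset([-0.3, 0.1, -0.5]) == [2, 0, 1]

    def test_absent_onsets_preserve_input_order_at_end(self):
        assert sort_by_onset([None, None, None]) == [0, 1, 2]
        assert sort_by_onset([0.2, None, -0.1]) == [2, 0, 1]

    def test_equal_onsets_break_ties_by_neuron_id(self):
        assert sort_by_onset([0.1, 0.1, 0.1], ["c", "a", "b"]) == [1, 2, 0]

    def _trace(self, values):
        v = np.asarray(values, dtype=float)
        return NormalizedActivityTrace("n", "stim", "all",
                                       np.arange(v.size) * 0.01, v,
                                       (-0.6, 0.0), 0.2, 10)

    def test_average_of_identical_traces_is_that_trace(self):
        tr = self._trace([0.2, 0.6, 0.9])
        t, v = population_average([tr, tr, tr])
        assert np.allclose(v, tr.values)

    def test_mirrored_pair_averages_to_indifference(self):
        up = self._trace([0.5, 0.8, 1.0, 0.7])
        down = self._trace(1.0 - up.values)
        _, v = population_average([up, down])
        assert np.allclose(v, 0.5)

    def test_grid_mismatch_rejected(self):
        a, b = self._trace([0.5, 0.6]), self._trace([0.5, 0.6, 0.7])
        with pytest.raises(ValueError):
            population_average([a, b])


def test_summarize_population_counts_and_consistency():
    rng = np.random.default_rng(13)
    n = 30
    cats = (["tonic_excitatory"] * 16 + ["tonic_suppressive"] * 5
            + ["unmodulated"] * 9)
    df = pd.DataFrame({
        "neuron_id": [f"n{i}" for i in range(n)],
        "tonic_category": cats,
        "fixation_response_roc": rng.uniform(0, 1, n),
        "reward_mod_cue_roc": rng.uniform(0, 1, n),
        "reward_mod_outcome_roc": rng.uniform(0, 1, n),
        "behavior_mod_roc": rng.uniform(0, 1, n),
        "onset_time_s": rng.uniform(-0.5, 0.5, n),
    })
    s = summarize_population(df, n_shuffles=500, seed=1)
    assert s.n_neurons == 30
    assert sum(s.category_counts.values()) == 30
    assert s.category_counts["tonic_excitatory"] == 16
    for c in s.correlations.values():
        assert c.rho is None or -1.0 <= c.rho <= 1.0
        if c.p_perm is not None:
            assert c.p_perm >= 1.0 / 501
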