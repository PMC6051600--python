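"""Index construction: rescaling, censored sums, stratified quantile flags,
summation, cutoffs and weighted prevalence."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import frailty_audit as fa
from frailty_audit.construction import weighted_quantile_threshold
from frailty_audit.variables import BURDEN_MODEL, FD_MODEL, BS_MODEL


class TestRescaleOrdinal:
    @pytest.mark.parametrize(
        "rank,k,expected",
        [
            (4, 5, 0.75),
            (1, 5, 0.0),
            (1, 3, 0.0),
            (2, 4, 1.0 / 3.0),
            (5, 5, 1.0),
            (2, 2, 1.0),  # dichotomous maps to {0, 1}
        ],
    )
    def test_linear_rule(self, rank, k, expected):
        assert fa.rescale_ordinal(rank, k) == pytest.approx(expected)

    def test_five_categories_exact_grid(self):
        got = fa.rescale_ordinal(np.arange(1, 6), 5)
        np.testing.assert_array_equal(got, [0.0, 0.25, 0.5, 0.75, 1.0])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fa.rescale_ordinal(0, 5)
        with pytest.raises(ValueError):
            fa.rescale_ordinal(6, 5)
        with pytest.raises(ValueError):
            fa.rescale_ordinal(1, 1)


class TestCensoredSum:
    @pytest.mark.parametrize(
        "values,expected", [([1, 1], 1.0), ([0, 0], 0.0), ([1, 0], 1.0)]
    )
    def test_cap_one(self, values, expected):
        # both problems: raw sum 2, one subtracted by the censoring
        assert fa.censored_sum(values, cap=1.0) == expected

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            fa.censored_sum([0.5, 1.0])


class TestQuantileFlags:
    def test_empirical_quintile_flags_lowest_two_of_ten(self):
        flags = fa.stratified_quantile_flag(
            np.arange(1, 11), np.zeros(10), q=0.2, direction="lowest"
        )
        np.testing.assert_array_equal(flags, [1, 1] + [0] * 8)

    def test_all_equal_values_flag_everyone(self):
        flags = fa.stratified_quantile_flag(
            np.full(8, 3.0), np.zeros(8), q=0.2, direction="lowest"
        )
        assert flags.sum() in (0, 8)
        assert flags.sum() == 8  # deterministic tie rule: ties all flagged

    def test_highest_direction(self):
        flags = fa.stratified_quantile_flag(
            np.arange(1, 11), np.zeros(10), q=0.2, direction="highest"
        )
        np.testing.assert_array_equal(flags, [0] * 8 + [1, 1])

    def test_unweighted_flags_overcover_weighted_population(self):
        # weights anti-correlated with the measure: the unweighted bottom
        # 20% carries far more than 20% of the total weight (the critique
        # of computing percentiles on unweighted survey data) while
        # weighted-mode thresholds restore ~20% coverage
        rng = np.random.default_rng(0)
        n = 5000
        values = rng.lognormal(1.0, 0.6, n)
        ranks = pd.Series(values).rank().to_numpy() / n
        weights = 0.2 + 4.0 * (1.0 - ranks) ** 2
        unweighted = fa.stratified_quantile_flag(values, np.zeros(n), q=0.2)
        weighted = fa.stratified_quantile_flag(
            values, np.zeros(n), q=0.2, weights=weights
        )
        cover_unw = np.sum(weights * unweighted) / weights.sum()
        cover_w = np.sum(weights * weighted) / weights.sum()
        assert cover_unw > 0.28
        assert abs(cover_w - 0.2) < weights.max() / weights.sum() + 1e-12

    def test_weighted_coverage_within_one_observation_weight(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=400)
        weights = rng.gamma(2.0, 1.0, 400)
        flags = fa.stratified_quantile_flag(
            values, np.zeros(400), q=0.2, weights=weights
        )
        cover = np.sum(weights * flags) / weights.sum()
        assert 0.2 - 1e-12 <= cover <= 0.2 + weights.max() / weights.sum()

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            weighted_quantile_threshold(np.array([np.nan, np.nan]), 0.2)

    def test_bad_q_rejected(self):
        with pytest.raises(ValueError):
            weighted_quantile_threshold(np.arange(5.0), 1.2)


class TestWeightedPrevalence:
    def test_equal_weights_is_mean(self):
        status = np.array([1, 0, 1, 0])
        assert fa.weighted_prevalence(status, np.ones(4)) == 0.5

    def test_two_row_example(self):
        assert fa.weighted_prevalence([1, 0], [1, 3]) == 0.25

    def test_matches_explicit_sum(self):
        rng = np.random.default_rng(2)
        status = rng.integers(0, 2, 100)
        w = rng.gamma(1.5, 1.0, 100)
        expected = sum(wi * si for wi, si in zip(w, status)) / sum(w)
        assert fa.weighted_prevalence(status, w) == pytest.approx(expected)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            fa.weighted_prevalence([1, 0], [0, 0])


class TestBuildIndex:
    def test_all_domains_zero_gives_zero_index(self, indexed_small):
        zero = indexed_small.copy()
        for m in (FD_MODEL, BS_MODEL):
            for d in m.domains:
                zero[f"domain__{d}"] = 0.0
        assert (fa.build_index(zero, FD_MODEL) == 0).all()
        assert (fa.build_index(zero, BS_MODEL) == 0).all()

    def test_burden_all_items_max_gives_one(self, indexed_small):
        full = indexed_small.copy()
        for item in BURDEN_MODEL.items:
            full[item] = 1.0
        assert (fa.build_index(full, BURDEN_MODEL) == 1.0).all()

    def test_fd_two_domains_meets_cutoff(self):
        table = pd.DataFrame(
            {
                "domain__physical": [1.0],
                "domain__weight_loss": [1.0],
                "domain__cognitive": [0.0],
                "domain__sensory": [0.0],
            }
        )
        idx = fa.build_index(table, FD_MODEL)
        assert idx.iloc[0] == 2.0
        assert fa.dichotomize(idx, FD_MODEL)[0] == 1

    def test_burden_order_invariance(self, indexed_small):
        shuffled = replace(BURDEN_MODEL, items=tuple(reversed(BURDEN_MODEL.items)))
        a = fa.build_index(indexed_small, BURDEN_MODEL)
        b = fa.build_index(indexed_small, shuffled)
        np.testing.assert_allclose(a, b)

    def test_constant_zero_item_changes_only_divisor(self, indexed_small):
        t = indexed_small.copy()
        t["extra_zero"] = 0.0
        extended = replace(BURDEN_MODEL, items=BURDEN_MODEL.items + ("extra_zero",))
        base = fa.build_index(t, BURDEN_MODEL)
        ext = fa.build_index(t, extended)
        np.testing.assert_allclose(ext, base * 24.0 / 25.0)


class TestDichotomize:
    @pytest.mark.parametrize(
        "value,model,expected",
        [
            (0.2, BURDEN_MODEL, 1),   # cutoff is inclusive
            (0.19, BURDEN_MODEL, 0),
            (3.0, BS_MODEL, 1),
            (2.0, FD_MODEL, 1),
            (1.99, FD_MODEL, 0),
        ],
    )
    def test_cutoffs(self, value, model, expected):
        assert fa.dichotomize([value], model)[0] == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fa.dichotomize([1.5], BURDEN_MODEL)


class TestBuilderProperties:
    def test_indices_lie_in_declared_ranges(self, indexed_small):
        for m in (FD_MODEL, BURDEN_MODEL, BS_MODEL):
            lo, hi = m.index_range
            idx = indexed_small[m.index_column]
            assert idx.between(lo, hi).all(), m.model_id

    @pytest.mark.parametrize("seed", [21, 22])
    def test_ranges_hold_across_seeds_and_loadings(self, seed):
        t = fa.generate_cohort(
            fa.CohortSpec(n_participants=600, seed=seed,
                          frailty_loading=0.5 + seed % 2)
        )
        x = fa.FrailtyIndexBuilder().fit(t).transform(t)
        for m in (FD_MODEL, BURDEN_MODEL, BS_MODEL):
            lo, hi = m.index_range
            assert x[m.index_column].between(lo, hi).all()

    def test_raising_a_deficit_never_lowers_status(self, cohort_small):
        builder = fa.FrailtyIndexBuilder().fit(cohort_small)
        base = builder.transform(cohort_small)
        bumped_input = cohort_small.copy()
        flip = bumped_input["poor_hearing"] == 0
        bumped_input["poor_hearing"] = 1
        bumped = builder.transform(bumped_input)
        for m in (FD_MODEL, BURDEN_MODEL, BS_MODEL):
            diff = bumped[m.status_column] - base[m.status_column]
            assert (diff >= 0).all(), m.model_id
        assert flip.any()

    def test_domain_values_in_unit_interval(self, indexed_small):
        from frailty_audit.variables import DOMAIN_COLUMNS
        for col in DOMAIN_COLUMNS:
            assert indexed_small[col].between(0, 1).all(), col

    def test_bs_slowness_matches_brute_force_stratum_quantile(self, indexed_small):
        # recompute one stratum's threshold by brute force
        t = indexed_small
        sub = t[(t["sex"] == "female") & (t["height_group"] == 0)]
        walk = np.sort(sub["walk_time_15ft"].to_numpy())[::-1]
        cut_count = sub["flag__slow_walk"].sum()
        # every flagged walk time must be >= every unflagged one
        flagged = sub[sub["flag__slow_walk"] == 1]["walk_time_15ft"]
        unflagged = sub[sub["flag__slow_walk"] == 0]["walk_time_15ft"]
        assert flagged.min() > unflagged.max() - 1e-12
        # coverage close to 20% of the stratum
        assert abs(cut_count / len(sub) - 0.2) < 0.02

    def test_sensory_domain_censors_both_problems(self, indexed_small):
        both = (indexed_small["poor_hearing"] == 1) & (
            indexed_small["poor_eyesight"] == 1
        )
        if both.any():
            assert (indexed_small.loc[both, "domain__sensory"] == 1.0).all()
            assert (indexed_small.loc[both, "sum__sensory"] == 2.0).all()
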