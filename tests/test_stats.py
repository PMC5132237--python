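import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellspan import (
    LifeHistoryDataset,
    SyntheticConfig,
    concentration_size_relation,
    conditional_age_correlation,
    feature_fold_increase,
    generate_population,
    km_estimate,
    logrank_test,
    median_split_at_age,
    pearson_r,
    per_age_lifespan_correlation,
    percent_median_difference,
    ranksum_test,
    total_fluorescence,
)

from conftest import make_cell
from oracles import exact_ranksum_pvalue


class TestPearson:
    def test_perfect_linear(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_perfect_inverse(self):
        assert pearson_r([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [2, 4, 6])

    @given(
        a=st.floats(0.1, 10), b=st.floats(-5, 5),
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        assert pearson_r(a * x + b, y) == pytest.approx(pearson_r(x, y))


class TestKaplanMeier:
    def test_hand_computed_curve(self):
        curve = km_estimate([1, 2, 3])
        np.testing.assert_allclose(curve.survival[curve.ages > 0], [2 / 3, 1 / 3, 0.0])
        assert curve.median == 2

    @given(st.lists(st.integers(1, 40), min_size=3, max_size=41))
    @settings(max_examples=50, deadline=None)
    def test_median_equals_sample_median_without_censoring(self, lifespans):
        if len(lifespans) % 2 == 0:
            lifespans.append(lifespans[0])  # odd n: sample median is unambiguous
        curve = km_estimate(lifespans)
        assert curve.median == np.median(lifespans)

    def test_survival_monotone_and_bounded(self, default_cohort):
        curve = km_estimate(default_cohort.lifespans())
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert curve.survival.min() >= 0 and curve.survival.max() <= 1

    def test_censoring_raises_median_above_naive(self):
        # true lifespans long, but half the observations are censored early
        times = [5, 6, 7, 8, 20, 22, 24, 26]
        events = [False, False, False, False, True, True, True, True]
        km = km_estimate(times, events)
        assert km.median > np.median(times)


class TestLogrank:
    def test_identical_groups_null(self):
        res = logrank_test([3, 5, 8, 13], [3, 5, 8, 13])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_invariance(self, default_cohort):
        ls = default_cohort.lifespans()
        a, b = ls[:60], ls[60:]
        r1 = logrank_test(a, b)
        r2 = logrank_test(b, a)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_small_fixture_hand_table(self):
        # groups A=[1,2,3], B=[2,3,4], all deaths. Hand life-table:
        # t=1: n=6 (3A,3B), 1 death in A; E_A = 3/6
        # t=2: n=5 (2A,3B), 2 deaths (1A,1B); E_A = 2*2/5
        # t=3: n=3 (1A,2B), 2 deaths (1A,1B); E_A = 2*1/3
        # t=4: n=1 (0A,1B), 1 death in B; E_A = 0
        # O_A - E_A = 3 - (0.5 + 0.8 + 2/3) = 1.0333...
        # Var = sum of hypergeometric variances:
        # t=1: 1*(3/6)*(3/6)*(6-1)/(6-1) = 0.25
        # t=2: 2*(2/5)*(3/5)*(5-2)/(5-1) = 0.36
        # t=3: 2*(1/3)*(2/3)*(3-2)/(3-1) = 0.2222...
        # chi2 = 1.0333^2 / 0.8322 = 1.2829
        res = logrank_test([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(1.0333333**2 / 0.8322222, rel=1e-4)

    def test_group_without_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [3, 4], events_b=[False, False])


class TestRanksum:
    def test_identical_samples(self):
        res = ranksum_test([1.0, 2.0, 3.0, 4.0, 5.0, 6.0] * 2, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0] * 2)
        assert res.p_value > 0.9

    @given(
        x=st.lists(st.integers(0, 1000), min_size=2, max_size=5, unique=True),
        y=st.lists(st.integers(1001, 2000), min_size=2, max_size=5, unique=True),
        shift=st.integers(-900, 0),
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_exact_enumeration(self, x, y, shift):
        y = [v + shift for v in y]
        if set(x) & set(y):
            return
        res = ranksum_test(x, y)
        assert res.method == "mannwhitney-exact"
        assert res.p_value == pytest.approx(exact_ranksum_pvalue(x, y))

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        res = ranksum_test(rng.normal(0, 1, 30), rng.normal(1, 1, 30))
        assert res.method == "mannwhitney-normal"
        assert res.p_value < 0.01


class TestPercentMedianDifference:
    @pytest.mark.parametrize("a, b, expect", [(17, 15, 13), (10, 10, 0), (30, 15, 100)])
    def test_values(self, a, b, expect):
        assert percent_median_difference(a, b) == expect

    def test_zero_reference(self):
        with pytest.raises(ZeroDivisionError):
            percent_median_difference(5, 0)


class TestTotalFluorescence:
    def test_product(self):
        assert total_fluorescence(2.0, 20.0) == 40.0
        assert total_fluorescence(0.0, 123.0) == 0.0

    def test_vectorized(self):
        out = total_fluorescence([1.0, 2.0], [10.0, 10.0])
        np.testing.assert_allclose(out, [10.0, 20.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            total_fluorescence(-1.0, 5.0)


class TestMedianSplit:
    def test_even_split(self):
        cells = [
            make_cell(f"c{i}", sizes=np.linspace(10, 10 + v, 5), times=np.arange(5.0))
            for i, v in enumerate([1, 2, 3, 4])
        ]
        ds = LifeHistoryDataset(cells=cells)
        feature = {c.cell_id: c.sizes for c in cells}
        split = median_split_at_age(ds, 5, feature)
        assert len(split.below_ids) == 2 and len(split.above_ids) == 2
        assert split.threshold == pytest.approx(np.median([11, 12, 13, 14]))

    def test_odd_population_splits_59_60_style(self, default_cohort):
        fold = feature_fold_increase(default_cohort)
        split = median_split_at_age(default_cohort, 5, fold)
        assert len(split.below_ids) == 59
        assert len(split.above_ids) == 60
        assert set(split.below_ids).isdisjoint(split.above_ids)

    def test_degenerate_split_flagged(self):
        cells = [
            make_cell(f"c{i}", sizes=[10.0, 10.0, 10.0], times=[0, 1, 2]) for i in range(4)
        ]
        ds = LifeHistoryDataset(cells=cells)
        feature = {c.cell_id: c.sizes for c in cells}
        split = median_split_at_age(ds, 2, feature)
        assert split.degenerate

    def test_age_beyond_all_cells_rejected(self, tiny_dataset):
        feature = {c.cell_id: c.sizes for c in tiny_dataset}
        with pytest.raises(ValueError):
            median_split_at_age(tiny_dataset, 50, feature)


class TestPerAgeCorrelation:
    def test_permutation_null_is_centred(self, large_cohort):
        """With lifespan labels shuffled among the cells alive at each age,
        the per-age correlations sit inside the null band |r| < 2/sqrt(n)
        at >= 95% of (age, permutation) pairs."""
        rng = np.random.default_rng(123)
        fold = feature_fold_increase(large_cohort)
        max_age = int(large_cohort.lifespans().max())
        results = []
        for _ in range(20):
            # age 1 is skipped: fold-increase is 1.0 for every cell there
            for age in range(2, max_age + 1):
                alive = [c for c in large_cohort.cells if c.rls >= age]
                if len(alive) < 30:
                    continue
                x = np.array([fold[c.cell_id][age - 1] for c in alive])
                y = rng.permutation([c.rls for c in alive]).astype(float)
                r = pearson_r(x, y)
                results.append(abs(r) < 2.0 / np.sqrt(len(alive)))
        assert np.mean(results) >= 0.93

    def test_min_n_respected(self, default_cohort):
        fold = feature_fold_increase(default_cohort)
        series = per_age_lifespan_correlation(default_cohort, fold, min_n=20)
        assert series.n.min() >= 20
        assert np.all(np.diff(series.n) <= 0)

    def test_exclude_post_sep_reduces_late_samples(self, default_cohort):
        fold = feature_fold_increase(default_cohort)
        full = per_age_lifespan_correlation(default_cohort, fold, min_n=10)
        pre = per_age_lifespan_correlation(
            default_cohort, fold, min_n=10, exclude_post_sep=True
        )
        common = np.intersect1d(full.ages, pre.ages)
        n_full = dict(zip(full.ages, full.n))
        n_pre = dict(zip(pre.ages, pre.n))
        assert all(n_pre[a] <= n_full[a] for a in common)
        late = [a for a in common if a >= 12]
        assert any(n_pre[a] < n_full[a] for a in late)

    def test_conditional_noop_at_zero(self, default_cohort):
        fold = feature_fold_increase(default_cohort)
        base = per_age_lifespan_correlation(default_cohort, fold)
        cond = conditional_age_correlation(default_cohort, fold, 0)
        np.testing.assert_allclose(base.r, cond.r)

    def test_correlations_bounded(self, default_cohort):
        fold = feature_fold_increase(default_cohort)
        series = per_age_lifespan_correlation(default_cohort, fold)
        assert np.all(np.abs(series.r) <= 1.0)


class TestConcentrationSize:
    def test_zero_dilution_gives_null_relation(self):
        cfg = SyntheticConfig(
            n_cells=500, seed=21,
            fluor_dilution=0.0, fluor_sep_surge=1.0,
            fluor_time_slope=0.0, fluor_lifespan_coupling=0.0,
        )
        ds = generate_population(cfg)
        r, slope, n = concentration_size_relation(ds, 5)
        assert n >= 400
        assert abs(r) < 0.1

    def test_dilution_gives_negative_relation_at_mid_age(self):
        cfg = SyntheticConfig(
            n_cells=500, seed=21,
            fluor_sep_surge=1.0, fluor_time_slope=0.0, fluor_lifespan_coupling=0.0,
        )
        ds = generate_population(cfg)
        r, _, _ = concentration_size_relation(ds, 8)
        assert r < -0.1

    def test_requires_fluorescence(self, tiny_dataset):
        with pytest.raises(ValueError):
            concentration_size_relation(tiny_dataset, 2)
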