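import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oracles import bh_stepup, taub_brute
from scrrobust import (
    Dataset,
    ResampleConfig,
    ValidationError,
    allocate_groups,
    bootstrap_dataset,
    category_mean_table,
    effect_size_trend,
    kendall_tau_b,
    pairwise_robustness,
    percentile_ci,
    size_sweep,
    strategy_effect_matrix,
    trend_analysis,
)
from scrrobust.robustness import STRATEGY_IDS, category_pairs
from statsmodels.stats.multitest import multipletests


class TestBootstrap:
    def test_single_source_row_reproduced(self, population):
        one = Dataset([population.ids[0]], population.responses[:1])
        for mode in ("phase_wise", "phase_only", "full_row"):
            boot = bootstrap_dataset(one, 5, mode, np.random.default_rng(1))
            for i in range(5):
                np.testing.assert_array_equal(
                    boot.responses[i], one.responses[0]
                )

    def test_full_row_membership(self, population):
        boot = bootstrap_dataset(
            population, 40, "full_row", np.random.default_rng(2)
        )
        source = {r.tobytes() for r in population.responses}
        assert all(r.tobytes() in source for r in boot.responses)

    def test_phase_wise_mixes_blocks_across_sources(self):
        # two very different rows: block provenance is identifiable, and the
        # ACQ-CSP and EXT_EARLY-CSP blocks should disagree about half the time
        r = np.zeros((2, 3, 5, 2))
        r[1] = 9.0
        src = Dataset(["lo", "hi"], r)
        boot = bootstrap_dataset(src, 4000, "phase_wise", np.random.default_rng(3))
        acq = boot.responses[:, 0, 0, 0] > 1
        ext = boot.responses[:, 1, 0, 0] > 1
        frac = np.mean(acq != ext)
        assert abs(frac - 0.5) < 0.03  # binomial SE ~ 0.008

    def test_phase_only_keeps_stimuli_together(self):
        r = np.zeros((2, 3, 5, 2))
        r[1] = 9.0
        src = Dataset(["lo", "hi"], r)
        boot = bootstrap_dataset(src, 500, "phase_only", np.random.default_rng(4))
        csp = boot.responses[:, 0, 0, 0] > 1
        csm = boot.responses[:, 0, 0, 1] > 1
        assert np.array_equal(csp, csm)

    def test_deterministic_given_rng_state(self, population):
        a = bootstrap_dataset(population, 20, "phase_wise", np.random.default_rng(7))
        b = bootstrap_dataset(population, 20, "phase_wise", np.random.default_rng(7))
        assert a.equals(b)

    def test_empty_source_rejected(self):
        empty = Dataset([], np.empty((0, 3, 5, 2)))
        with pytest.raises(ValidationError):
            bootstrap_dataset(empty, 5, "full_row", np.random.default_rng(0))


class TestAllocation:
    def test_exact_split(self):
        labels = allocate_groups(30, 3, np.random.default_rng(0))
        assert sorted(np.bincount(labels)[1:]) == [10, 10, 10]

    def test_remainder_split(self):
        labels = allocate_groups(2000, 3, np.random.default_rng(1))
        assert sorted(np.bincount(labels)[1:]) == [666, 667, 667]

    def test_n_below_k_rejected(self):
        with pytest.raises(ValidationError):
            allocate_groups(2, 3, np.random.default_rng(0))

    def test_positionwise_uniformity(self):
        # label frequencies at a fixed position should be uniform over draws
        rng = np.random.default_rng(11)
        first = [allocate_groups(9, 3, rng)[0] for _ in range(900)]
        counts = np.bincount(first)[1:]
        chi2 = ((counts - 300.0) ** 2 / 300.0).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=2)


class TestKendall:
    def test_perfect_and_reversed(self):
        assert kendall_tau_b([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert kendall_tau_b([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_worked_example(self):
        assert kendall_tau_b([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(1 / 3)

    def test_all_tied_vector_rejected(self):
        with pytest.raises(ValidationError):
            kendall_tau_b([1, 1, 1], [1, 2, 3])

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=12),
        st.data(),
    )
    def test_matches_all_pairs_enumeration(self, x, data):
        y = data.draw(
            st.lists(st.integers(0, 5), min_size=len(x), max_size=len(x))
        )
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        assert kendall_tau_b(x, y) == pytest.approx(
            taub_brute(x, y), abs=1e-12
        )


class TestPercentileCi:
    def test_constant_samples(self):
        assert percentile_ci(np.full(10, 3.3)) == (3.3, 3.3)

    def test_interpolated_order_statistics(self):
        lo, hi = percentile_ci(np.arange(1, 1001, dtype=float))
        assert lo == pytest.approx(25.975)
        assert hi == pytest.approx(975.025)

    def test_low_not_above_high(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            lo, hi = percentile_ci(rng.normal(size=17))
            assert lo <= hi


class TestEffectMatrix:
    def test_shape_and_determinism(self, population):
        cfg = ResampleConfig(
            sizes=(30,), n_resamples=10, n_ci_boot=20, seed=5
        )
        a = strategy_effect_matrix(population, 30, cfg, 0)
        b = strategy_effect_matrix(population, 30, cfg, 0)
        assert a.values.shape == (10, 15)
        np.testing.assert_array_equal(a.values, b.values)

    def test_null_eta_shrinks_with_size(self, population):
        cfg = ResampleConfig(
            sizes=(30, 240), n_resamples=40, n_ci_boot=20, seed=6
        )
        small = strategy_effect_matrix(population, 30, cfg, 0)
        large = strategy_effect_matrix(population, 240, cfg, 1)
        assert np.nanmean(small.values) > np.nanmean(large.values)

    def test_null_mean_matches_beta_expectation(self, population):
        # under H0, eta_p2 ~ Beta(df1/2, df2/2) so its mean is df1/(df1+df2);
        # check the one-way EXT.4 strategy at N=30: df1=2, df2=27
        cfg = ResampleConfig(sizes=(30,), n_resamples=200, n_ci_boot=20, seed=7)
        mat = strategy_effect_matrix(population, 30, cfg, 0)
        col = mat.column("EXT.4")
        expected = 2 / 29
        se = np.nanstd(col, ddof=1) / np.sqrt(np.sum(~np.isnan(col)))
        assert abs(np.nanmean(col) - expected) < 4 * se


class TestPairwise:
    def test_pair_families(self):
        pairs = category_pairs()
        counts = pd.Series([c for c, _, _ in pairs]).value_counts()
        assert counts["ACQ_EXT"] == 6
        assert counts["EXT"] == 21
        assert counts["EXT_EXT"] == 6

    def test_identical_columns_give_tau_one(self, population):
        cfg = ResampleConfig(sizes=(30,), n_resamples=30, n_ci_boot=50, seed=8)
        mat = strategy_effect_matrix(population, 30, cfg, 0)
        # force two strategies identical
        j = STRATEGY_IDS.index("EXT_EXT.4")
        mat.values[:, j] = mat.column("EXT_EXT.3")
        pw = pairwise_robustness(mat, cfg)
        row = pw[
            (pw.strategy_a == "EXT_EXT.3") & (pw.strategy_b == "EXT_EXT.4")
        ].iloc[0]
        assert row["mean_taub"] == pytest.approx(1.0)
        assert row["ci_low"] == pytest.approx(1.0)
        assert row["ci_high"] == pytest.approx(1.0)

    def test_independent_columns_give_tau_near_zero(self):
        rng = np.random.default_rng(9)
        n = 100
        x, y = rng.normal(size=n), rng.normal(size=n)
        tau = kendall_tau_b(x, y)
        # null SD of tau_b is ~ sqrt(2(2n+5)/(9n(n-1)))
        sd = np.sqrt(2 * (2 * n + 5) / (9 * n * (n - 1)))
        assert abs(tau) < 4 * sd


class TestSweepAndTrends:
    def test_reduced_sweep_is_seed_reproducible(self, population):
        cfg = ResampleConfig(
            sizes=(30, 60), n_resamples=12, n_ci_boot=30, seed=10
        )
        a = size_sweep(population, cfg)
        b = size_sweep(population, cfg)
        pd.testing.assert_frame_equal(a.pairwise, b.pairwise)
        assert len(a.pairwise) == 2 * (6 + 21 + 6)

    def test_trend_r_is_one_for_monotone_taub(self):
        rows = []
        for i, size in enumerate((30, 60, 120, 240)):
            for cat, a, b in category_pairs():
                rows.append(
                    {
                        "size": size,
                        "category": cat,
                        "strategy_a": a,
                        "strategy_b": b,
                        "mean_taub": size / 1000.0 if a == "EXT.1" else 0.5,
                    }
                )
        out = trend_analysis(pd.DataFrame(rows))
        increasing = out[out.strategy_a == "EXT.1"]
        assert np.allclose(increasing["r"], 1.0)
        constant = out[out.strategy_a != "EXT.1"]
        assert constant["r"].isna().all()

    def test_bh_flags_match_step_up_rule(self):
        pvals = np.array([0.01, 0.02, 0.2, 0.9])
        ours = multipletests(pvals, alpha=0.1, method="fdr_bh")[0]
        np.testing.assert_array_equal(ours, bh_stepup(pvals, 0.1))
        np.testing.assert_array_equal(ours, [True, True, False, False])

    def test_effect_size_trend_negative_under_null(self, population):
        cfg = ResampleConfig(
            sizes=(30, 120, 480), n_resamples=25, n_ci_boot=10, seed=12
        )
        sweep = size_sweep(population, cfg, compute_pairwise=False)
        trend = effect_size_trend(sweep)
        assert (trend["r"] < 0).all()
        means = category_mean_table(sweep)
        wide = means.pivot(index="size", columns="category", values="mean_eta_p2")
        assert (wide.loc[30] > wide.loc[480]).all()

    def test_full_row_mode_shows_same_decrease(self, population):
        cfg = ResampleConfig(
            sizes=(30, 60, 90), n_resamples=25, n_ci_boot=10,
            mode="full_row", seed=13,
        )
        sweep = size_sweep(population, cfg, compute_pairwise=False)
        trend = effect_size_trend(sweep)
        assert (trend["r"] < 0).all()

    def test_trend_needs_three_sizes(self, population):
        cfg = ResampleConfig(sizes=(30, 60), n_resamples=5, n_ci_boot=5, seed=1)
        sweep = size_sweep(population, cfg, compute_pairwise=False)
        with pytest.raises(ValidationError):
            effect_size_trend(sweep)
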