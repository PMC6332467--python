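"""Exact tests, residual post-hoc, ANOVA and Dunnett against independent oracles."""

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from mtvarload.stats import (
    ContingencyTable,
    adjusted_residuals,
    anova_oneway_raw,
    anova_oneway_summary,
    bonferroni_adjust,
    dunnett_two_tailed,
    fisher_exact_2x2,
    freeman_halton_exact,
    summarize_groups,
    _dunnett_null_max_abs_t,
    _enumerate_log_probs,
    _log_point_prob_const,
)

COHORT_HAPLOGROUP_COUNTS = {
    # haplogroup: (t2dm, obesity, atherosclerosis, control)
    "C": (1, 0, 1, 1), "D": (0, 1, 0, 2), "G": (0, 0, 1, 0), "H": (42, 37, 40, 43),
    "HV": (0, 1, 1, 2), "I": (5, 2, 3, 1), "J": (9, 13, 10, 7), "K": (4, 6, 3, 6),
    "N": (0, 2, 2, 0), "R": (1, 0, 0, 2), "T": (10, 14, 14, 8), "U": (22, 12, 15, 30),
    "V": (1, 6, 3, 8), "W": (3, 3, 6, 3), "X": (2, 3, 1, 2),
}


def pair_table(col: int) -> ContingencyTable:
    labels = sorted(COHORT_HAPLOGROUP_COUNTS)
    rows = [[COHORT_HAPLOGROUP_COUNTS[l][col], COHORT_HAPLOGROUP_COUNTS[l][3]] for l in labels]
    return ContingencyTable.from_rows(rows, labels, ("disease", "control"))


small_2x2 = st.tuples(
    st.integers(0, 25), st.integers(0, 25), st.integers(0, 25), st.integers(0, 25)
).filter(lambda t: sum(t) > 0)


class TestFisher2x2:
    @pytest.mark.parametrize(
        "rows, expected",
        [
            ([[65, 35], [58, 57]], 0.038),  # carriers >0.5, atherosclerosis
            ([[59, 41], [58, 57]], 0.220),
            ([[58, 42], [58, 57]], 0.276),
            ([[8, 92], [11, 104]], 0.811),
            ([[10, 90], [11, 104]], 1.0),
            ([[22, 27], [3, 5]], 1.0),  # unique rare/common tables
            ([[14, 28], [4, 9]], 1.0),
            ([[26, 28], [2, 4]], 0.675),
        ],
    )
    def test_published_tables(self, rows, expected):
        res = fisher_exact_2x2(ContingencyTable.from_rows(rows))
        assert round(res.p_value, 3) == expected

    def test_balanced_table(self):
        assert fisher_exact_2x2(ContingencyTable.from_rows([[1, 1], [1, 1]])).p_value == 1.0

    def test_degenerate_margin(self):
        res = fisher_exact_2x2(ContingencyTable.from_rows([[0, 0], [3, 5]]))
        assert res.p_value == 1.0 and res.degenerate

    @settings(deadline=None, max_examples=60)
    @given(small_2x2)
    def test_matches_scipy_and_symmetries(self, cells):
        a, b, c, d = cells
        tab = ContingencyTable.from_rows([[a, b], [c, d]])
        res = fisher_exact_2x2(tab)
        rt, ct = tab.row_totals, tab.col_totals
        if (rt == 0).any() or (ct == 0).any():
            assert res.degenerate
            return
        assert res.p_value == pytest.approx(
            sps.fisher_exact([[a, b], [c, d]])[1], rel=1e-9, abs=1e-12
        )
        for other in ([[c, d], [a, b]], [[b, a], [d, c]], [[a, c], [b, d]]):
            assert fisher_exact_2x2(
                ContingencyTable.from_rows(other)
            ).p_value == pytest.approx(res.p_value, rel=1e-12)


class TestFreemanHalton:
    @pytest.mark.parametrize(
        "rows, expected",
        [
            ([[41, 57], [30, 31], [29, 27]], 0.434),  # 0/1/2+ carrier categories
            ([[42, 57], [22, 31], [36, 27]], 0.134),
            ([[35, 57], [31, 31], [34, 27]], 0.083),
        ],
    )
    def test_published_3x2_tables(self, rows, expected):
        res = freeman_halton_exact(ContingencyTable.from_rows(rows))
        assert res.method == "full-enumeration"
        assert round(res.p_value, 3) == expected

    def test_reduces_to_fisher_on_2x2(self):
        tab = ContingencyTable.from_rows([[65, 35], [58, 57]])
        assert freeman_halton_exact(tab).p_value == pytest.approx(
            fisher_exact_2x2(tab).p_value, abs=1e-12
        )

    def test_enumerated_probabilities_sum_to_one(self):
        tab = ContingencyTable.from_rows([[8, 3], [2, 9], [5, 5]])
        const = _log_point_prob_const(tab.row_totals, tab.col_totals)
        log_probs = _enumerate_log_probs(tab.row_totals, tab.col_totals, const)
        assert np.exp(log_probs).sum() == pytest.approx(1.0, abs=1e-9)

    def test_monte_carlo_agrees_with_enumeration(self):
        tab = ContingencyTable.from_rows([[12, 8], [5, 15], [10, 10]])
        exact = freeman_halton_exact(tab)
        assert exact.method == "full-enumeration"
        mc = freeman_halton_exact(tab, max_enumeration=1, mc_replicates=100_000, seed=3)
        assert mc.method == "monte-carlo"
        assert abs(mc.p_value - exact.p_value) <= 3 * mc.std_error

    def test_large_table_uses_monte_carlo_with_metadata(self):
        res = freeman_halton_exact(pair_table(0), mc_replicates=10_000, seed=5)
        assert res.method == "monte-carlo"
        assert res.replicates == 10_000 and res.seed == 5
        assert res.std_error is not None and res.p_value > 0

    def test_replicate_floor(self):
        with pytest.raises(ValueError, match="mc_replicates"):
            freeman_halton_exact(pair_table(0), mc_replicates=10)

    def test_zero_rows_dropped(self):
        # rows with zero totals carry no information
        with_zero = ContingencyTable.from_rows([[3, 4], [0, 0], [5, 2]])
        without = ContingencyTable.from_rows([[3, 4], [5, 2]])
        assert freeman_halton_exact(with_zero).p_value == pytest.approx(
            freeman_halton_exact(without).p_value
        )


class TestAdjustedResiduals:
    @pytest.mark.parametrize(
        "col, label, resid, phi",
        [
            (0, "V", -2.18, -0.148),  # T2DM vs control
            (1, "U", -2.60, -0.177),  # obesity vs control
            (2, "U", -1.99, -0.136),  # atherosclerosis vs control
        ],
    )
    def test_published_cells(self, col, label, resid, phi):
        rep = adjusted_residuals(pair_table(col))
        assert round(rep.residuals.loc[label, "disease"], 2) == resid
        assert round(rep.phi.loc[label, "disease"], 3) == phi

    def test_published_cell_p_value(self):
        rep = adjusted_residuals(pair_table(0))
        assert round(rep.p_values.loc["V", "disease"], 5) == pytest.approx(0.02961, abs=2e-5)

    def test_observed_minus_expected_sums_to_zero(self):
        rep = adjusted_residuals(pair_table(2))
        diff = rep.observed - rep.expected
        assert np.allclose(diff.sum(axis=1), 0, atol=1e-9)
        assert np.allclose(diff.sum(axis=0), 0, atol=1e-9)

    def test_2x2_residual_equals_sqrt_chi2(self):
        rows = [[65, 35], [58, 57]]
        rep = adjusted_residuals(ContingencyTable.from_rows(rows))
        chi2 = sps.chi2_contingency(rows, correction=False)[0]
        assert np.allclose(np.abs(rep.residuals.to_numpy()), np.sqrt(chi2))
        # phi is the signed sqrt(chi2/N) in the 2x2 case
        n = sum(map(sum, rows))
        assert abs(rep.phi.iloc[0, 0]) == pytest.approx(np.sqrt(chi2 / n))

    def test_zero_total_rows_undefined(self):
        rep = adjusted_residuals(ContingencyTable.from_rows([[3, 4], [0, 0]]))
        assert rep.residuals.iloc[1].isna().all()


class TestAnova:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = anova_oneway_raw([g, list(g)])
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_two_pass_oracle_and_scipy(self):
        rng = np.random.default_rng(2)
        groups = [list(rng.normal(m, 1.0, size=n)) for m, n in [(0, 12), (0.4, 9), (1.0, 15)]]
        res = anova_oneway_raw(groups)
        # two-pass textbook oracle
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
        f_oracle = (ssb / 2) / (ssw / (len(allv) - 3))
        assert res.f_statistic == pytest.approx(f_oracle, rel=1e-10)
        f_sp, p_sp = sps.f_oneway(*groups)
        assert res.f_statistic == pytest.approx(f_sp, rel=1e-10)
        assert res.p_value == pytest.approx(p_sp, rel=1e-9)

    def test_summary_equals_raw(self):
        rng = np.random.default_rng(3)
        groups = [list(rng.normal(0, 1, size=10)), list(rng.normal(0.5, 2, size=14))]
        raw = anova_oneway_raw(groups)
        summ = anova_oneway_summary(*summarize_groups(groups))
        assert raw.f_statistic == summ.f_statistic
        assert raw.p_value == summ.p_value

    def test_degenerate_zero_variance(self):
        res = anova_oneway_raw([[1.0, 1.0], [1.0, 1.0]])
        assert res.degenerate and res.p_value is None

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            anova_oneway_summary([10, 10], [0.1], [1.0, 1.0])


class TestDunnett:
    def test_single_comparison_equals_pooled_t(self):
        rng = np.random.default_rng(4)
        control = list(rng.normal(0, 1, 40))
        treat = list(rng.normal(0.5, 1, 35))
        res = dunnett_two_tailed([control, treat], control_index=0, seed=9)
        t_sp, p_sp = sps.ttest_ind(treat, control, equal_var=True)
        assert res.t_statistics[0] == pytest.approx(t_sp, rel=1e-10)
        se = max(res.std_errors[0], 1e-4)
        assert abs(res.p_adjusted[0] - p_sp) <= 4 * se

    def test_identical_groups_p_near_one(self):
        g = list(np.linspace(0, 1, 20))
        res = dunnett_two_tailed([g, list(g), list(g)], seed=0)
        assert all(p > 0.95 for p in res.p_adjusted)

    def test_adjusted_geq_unadjusted_and_monotone(self):
        rng = np.random.default_rng(8)
        groups = [list(rng.normal(m, 1, 30)) for m in (0, 0.3, 0.8, 0.1)]
        res = dunnett_two_tailed(groups, control_index=0, seed=2)
        df = res.df
        for t, p_adj in zip(res.t_statistics, res.p_adjusted):
            p_un = 2 * sps.t.sf(abs(t), df)
            assert p_adj >= p_un - 3 * max(res.std_errors)
        order = np.argsort([abs(t) for t in res.t_statistics])
        ps = [res.p_adjusted[i] for i in order]
        assert all(ps[i] >= ps[i + 1] - 1e-12 for i in range(len(ps) - 1))

    def test_matches_scipy_dunnett(self):
        rng = np.random.default_rng(12)
        control = rng.normal(0, 1, 50)
        t1 = rng.normal(0.4, 1, 45)
        t2 = rng.normal(-0.2, 1, 55)
        res = dunnett_two_tailed(
            [list(control), list(t1), list(t2)], control_index=0, seed=21
        )
        sp = sps.dunnett(t1, t2, control=control, alternative="two-sided")
        for mine, theirs in zip(res.p_adjusted, sp.pvalue):
            assert abs(mine - theirs) <= 0.01

    def test_familywise_error_at_critical_value_from_quadrature_oracle(self):
        """Balanced 3-vs-control design: the alpha=0.05 critical value from an
        independent quadrature oracle gives family-wise rejection 0.05."""
        from conftest import dunnett_critical_value

        n, k, df = 20, 3, 4 * 20 - 4
        d_crit = dunnett_critical_value(k, df)
        max_abs = _dunnett_null_max_abs_t([n] * k, n, df, replicates=200_000, seed=7)
        rate = float((max_abs >= d_crit).mean())
        se = np.sqrt(0.05 * 0.95 / 200_000)
        assert abs(rate - 0.05) <= 3 * se

    def test_control_too_small(self):
        with pytest.raises(ValueError):
            dunnett_two_tailed([[1.0], [1.0, 2.0, 3.0]], control_index=0)


class TestBonferroni:
    def test_explains_loss_of_significance(self):
        # the strongest haplogroup cell p-value does not survive 15 tests
        assert bonferroni_adjust([0.02961], 15)[0] == pytest.approx(0.44415)

    def test_capped_at_one(self):
        assert bonferroni_adjust([0.5], 2) == [1.0]

    def test_zero_stays_zero(self):
        assert bonferroni_adjust([0.0], 1000) == [0.0]

    def test_family_size_floor(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2], 1)
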