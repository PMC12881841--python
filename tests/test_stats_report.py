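"""Reporting statistics: normality gate, two-way ANOVA with Šídák pairwise
comparisons, Welch's t, and the response table."""

import numpy as np
import pytest
from scipy import stats

from gabaclamp.errors import DataError, DesignError
from gabaclamp.stats_report import (
    normality_check,
    response_table,
    sidak_adjust,
    two_way_anova,
    welch_t,
)


class TestNormalityCheck:
    def test_type_one_rate_under_the_null(self, rng):
        rejections = sum(
            not normality_check(rng.normal(0, 1, 50)).normal for _ in range(400)
        )
        rate = rejections / 400
        # 0.05 ± 3·binomial SE
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 400)

    def test_power_against_heavy_tails(self, rng):
        rejections = sum(
            not normality_check(rng.standard_t(1, 50)).normal for _ in range(100)
        )
        assert rejections / 100 > 0.9

    def test_decision_drives_reporting_style(self, rng):
        d = normality_check(rng.normal(0, 1, 60))
        assert d.report_as == ("mean±SEM" if d.normal else "median±IQR")

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DataError):
            normality_check(np.full(20, 3.0))


def _balanced_anova_oracle(y, a, t):
    """Classical closed-form two-way decomposition (balanced designs)."""
    y, a, t = np.asarray(y), np.asarray(a), np.asarray(t)
    levels_a, levels_t = np.unique(a), np.unique(t)
    cells = {(ai, ti): y[(a == ai) & (t == ti)] for ai in levels_a for ti in levels_t}
    n = len(next(iter(cells.values())))
    gm = y.mean()
    ma = {ai: y[a == ai].mean() for ai in levels_a}
    mt = {ti: y[t == ti].mean() for ti in levels_t}
    ss_a = sum(2 * n * (ma[ai] - gm) ** 2 for ai in levels_a)
    ss_t = sum(2 * n * (mt[ti] - gm) ** 2 for ti in levels_t)
    ss_i = sum(
        n * (cells[k].mean() - ma[k[0]] - mt[k[1]] + gm) ** 2 for k in cells
    )
    ss_e = sum(((cells[k] - cells[k].mean()) ** 2).sum() for k in cells)
    mse = ss_e / (4 * (n - 1))
    return ss_a / mse, ss_t / mse, ss_i / mse


class TestTwoWayAnova:
    def _design(self, n):
        ages = ["three_week"] * (2 * n) + ["adult"] * (2 * n)
        trts = (["VEH"] * n + ["PNA"] * n) * 2
        return ages, trts

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_balanced_design_matches_closed_form_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ages, trts = self._design(12)
        y = rng.normal(0, 1, 48)
        res = two_way_anova(y, ages, trts)
        fa, ft, fi = _balanced_anova_oracle(y, ages, trts)
        assert res.effects.loc["age", "F"] == pytest.approx(fa, rel=1e-9)
        assert res.effects.loc["treatment", "F"] == pytest.approx(ft, rel=1e-9)
        assert res.effects.loc["interaction", "F"] == pytest.approx(fi, rel=1e-9)
        assert res.residual_df == 44

    def test_null_p_values_are_uniform(self, rng):
        ages, trts = self._design(6)
        ps = [
            two_way_anova(rng.normal(0, 1, 24), ages, trts).effects.loc["age", "p"]
            for _ in range(300)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_power_for_a_two_sd_age_effect(self, rng):
        ages, trts = self._design(12)
        shift = np.array([2.0 if a == "adult" else 0.0 for a in ages])
        hits = sum(
            two_way_anova(rng.normal(0, 1, 48) + shift, ages, trts).effects.loc[
                "age", "p"
            ]
            < 0.05
            for _ in range(60)
        )
        assert hits / 60 > 0.9

    def test_unbalanced_design_runs_and_reports_four_contrasts(self, rng):
        ages = ["three_week"] * 20 + ["adult"] * 26
        trts = ["VEH"] * 12 + ["PNA"] * 8 + ["VEH"] * 14 + ["PNA"] * 12
        res = two_way_anova(rng.normal(0, 1, 46), ages, trts)
        assert len(res.pairwise) == 4
        assert ((res.pairwise["p_sidak"] >= res.pairwise["p_raw"]) | (res.pairwise["p_raw"] > 0.999)).all()

    def test_empty_cell_is_a_design_error(self, rng):
        ages = ["three_week"] * 10 + ["adult"] * 5
        trts = ["VEH"] * 5 + ["PNA"] * 5 + ["VEH"] * 5
        with pytest.raises(DesignError):
            two_way_anova(rng.normal(0, 1, 15), ages, trts)


def test_sidak_closed_form():
    assert sidak_adjust(0.05, k=4) == pytest.approx(1.0 - 0.95**4)
    # adjusted alpha for familywise 0.05 over 4 comparisons
    alpha_adj = 1.0 - (1.0 - 0.05) ** (1 / 4)
    assert sidak_adjust(alpha_adj, k=4) == pytest.approx(0.05)


class TestWelchT:
    def test_identical_samples_give_t_zero_p_one(self):
        x = np.arange(10.0)
        res = welch_t(x, x)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_brute_force_formula(self, rng):
        a, b = rng.normal(0, 1, 11), rng.normal(0.4, 2.0, 14)
        res = welch_t(a, b)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p = 2 * stats.t.sf(abs(t), df)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_single_observation_is_an_error(self):
        with pytest.raises(DataError):
            welch_t([1.0], [1.0, 2.0, 3.0])


class TestResponseTable:
    def _labels(self):
        # three_week_VEH: one all-PSP cell, one all-AP cell, one mixed cell
        return {
            "c1": ("three_week_VEH", {"g10_tau7": ["psp_only"] * 10}),
            "c2": ("three_week_VEH", {"g10_tau7": ["ap_rising"] * 10}),
            "c3": (
                "three_week_VEH",
                {"g10_tau7": ["psp_only"] * 6 + ["ap_delayed"] * 3 + ["baseline_fail"]},
            ),
            "c4": ("adult_VEH", {"g10_tau7": ["psp_only"] * 10}),
        }

    def test_counts_and_partition(self):
        df = response_table(self._labels())
        row = df[(df.group == "three_week_VEH") & (df.condition == "g10_tau7")].iloc[0]
        assert (row.PSP, row.AP, row.Both) == (1, 1, 1)
        assert row.total == row.PSP + row.AP + row.Both

    def test_empty_condition_has_zero_row_without_division_error(self):
        df = response_table(self._labels())
        row = df[(df.group == "adult_PNA") & (df.condition == "g10_tau7")].iloc[0]
        assert row.total == 0 and row.pct_with_ap == 0.0

    def test_percentage_recomputes_from_counts(self):
        # 32 of 107 spiking cells -> 29.9%
        labels = {}
        for i in range(107):
            lab = ["ap_rising"] * 10 if i < 32 else ["psp_only"] * 10
            labels[f"c{i}"] = ("adult_PNA", {"g10_tau10": lab})
        df = response_table(labels)
        row = df[(df.group == "adult_PNA") & (df.condition == "g10_tau10")].iloc[0]
        assert row.pct_with_ap == pytest.approx(29.9, abs=0.05)
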