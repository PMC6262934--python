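"""The statistical engine against closed-form and scipy/statsmodels oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from orchidatlas.errors import InputError
from orchidatlas.stats import (
    collecting_effort,
    diversity_vs_area,
    effort_family_contrast,
    linear_regression,
    one_way_anova,
    tukey_hsd,
)

from conftest import make_frame


class TestLinearRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        reg = linear_regression(x, 2 * x + 1)
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(1.0)
        assert reg.r_squared == pytest.approx(1.0)

    def test_constant_y_null_fit(self):
        reg = linear_regression(np.arange(10.0), np.full(10, 3.0))
        assert reg.slope == 0.0
        assert reg.r_squared == 0.0
        assert reg.f_stat == 0.0
        assert reg.p_value == 1.0

    def test_fuzz_against_normal_equation_and_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + rng.normal() * x
            reg = linear_regression(x, y)
            # closed-form normal equations
            X = np.column_stack([np.ones(n), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert reg.intercept == pytest.approx(beta[0], rel=1e-10, abs=1e-12)
            assert reg.slope == pytest.approx(beta[1], rel=1e-10, abs=1e-12)
            fit = sm.OLS(y, X).fit()
            assert reg.r_squared == pytest.approx(fit.rsquared, rel=1e-9, abs=1e-12)
            assert reg.f_stat == pytest.approx(fit.fvalue, rel=1e-9)
            assert reg.p_value == pytest.approx(fit.f_pvalue, rel=1e-9, abs=1e-15)
            assert reg.df == (1, n - 2)

    def test_log_transform_errors_on_nonpositive(self):
        with pytest.raises(InputError, match="element 1"):
            linear_regression([1.0, -2.0, 3.0], [1.0, 2.0, 3.0], "log10_x")

    def test_zero_x_variance_rejected(self):
        with pytest.raises(InputError):
            linear_regression([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_log10_both_linearizes_power_law(self):
        x = np.array([1.0, 10.0, 100.0, 1000.0])
        reg = linear_regression(x, 5 * x**0.7, "log10_both")
        assert reg.slope == pytest.approx(0.7)
        assert reg.r_squared == pytest.approx(1.0)


class TestOneWayAnova:
    def test_identical_groups_f_zero_p_one(self):
        res = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.f_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_all_values_identical_not_nan(self):
        res = one_way_anova([[2.0, 2.0], [2.0, 2.0]])
        assert res.f_stat == 0.0
        assert res.p_value == 1.0

    def test_two_groups_equal_pooled_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=12), rng.normal(1.0, size=9)
        res = one_way_anova([a, b])
        t, p = sps.ttest_ind(a, b)
        assert res.f_stat == pytest.approx(t**2, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_ss_decomposition_conserved(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1, size=n) for m, n in [(0, 5), (1, 8), (2, 3)]]
        res = one_way_anova(groups)
        total = np.concatenate(groups)
        ss_total = ((total - total.mean()) ** 2).sum()
        assert res.ss_between + res.ss_within == pytest.approx(ss_total, rel=1e-9)

    def test_fuzz_against_scipy_f_oneway(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            groups = [rng.normal(size=int(rng.integers(2, 20))) for _ in range(k)]
            res = one_way_anova(groups)
            f, p = sps.f_oneway(*groups)
            assert res.f_stat == pytest.approx(f, rel=1e-9)
            assert res.p_value == pytest.approx(p, rel=1e-9, abs=1e-15)

    def test_degenerate_layouts_rejected(self):
        with pytest.raises(InputError):
            one_way_anova([[1.0, 2.0]])
        with pytest.raises(InputError):
            one_way_anova([[1.0], [2.0]])
        with pytest.raises(InputError):
            one_way_anova([[], [1.0, 2.0]])


class TestTukey:
    def test_two_equal_groups_p_equals_anova_p(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=10), rng.normal(0.8, size=10)
        tk = tukey_hsd([a, b], ["a", "b"])
        anova = one_way_anova([a, b])
        assert tk.comparisons[0].p_adjusted == pytest.approx(anova.p_value, rel=1e-7)

    def test_identical_groups_p_one(self):
        tk = tukey_hsd([[1.0, 2.0, 3.0]] * 3)
        assert all(c.p_adjusted == 1.0 for c in tk.comparisons)
        assert not any(c.significant for c in tk.comparisons)

    def test_fuzz_against_scipy_tukey_hsd(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            groups = [rng.normal(size=int(rng.integers(3, 15))) for _ in range(k)]
            tk = tukey_hsd(groups, [f"g{i}" for i in range(k)])
            oracle = sps.tukey_hsd(*groups)
            for c in tk.comparisons:
                i, j = int(c.group_i[1:]), int(c.group_j[1:])
                assert c.p_adjusted == pytest.approx(
                    oracle.pvalue[i, j], rel=1e-6, abs=1e-12
                )
                assert c.mean_diff == pytest.approx(
                    groups[i].mean() - groups[j].mean(), rel=1e-12
                )

    def test_singleton_groups_excluded(self):
        tk = tukey_hsd([[1.0], [1.0, 2.0], [3.0, 4.0]], ["s", "a", "b"])
        assert tk.excluded_groups == ["s"]
        assert len(tk.comparisons) == 1


class TestCollectingEffort:
    def test_well_collected_genus_arithmetic(self):
        # a genus of 15 species with 4,584 records: effort = log10(305.6)
        rows = []
        for i in range(15):
            n = 306 if i < 9 else 305  # 9*306 + 6*305 = 4584
            rows += [
                {"scientificName": f"Acianthus sp{i}", "genus": "Acianthus"}
            ] * n
        frame = make_frame(rows)
        table = collecting_effort(frame, "genus").set_index("taxon")
        assert table.loc["Acianthus", "n_records"] == 4584
        assert table.loc["Acianthus", "effort"] == pytest.approx(
            math.log10(4584 / 15)
        )
        assert table.loc["Acianthus", "effort"] == pytest.approx(2.485, abs=5e-4)

    def test_records_equal_species_gives_zero(self):
        frame = make_frame(
            [{"scientificName": f"A sp{i}", "genus": "A"} for i in range(4)]
        )
        assert collecting_effort(frame, "genus")["effort"].iloc[0] == 0.0

    def test_counts_match_group_by_oracle(self, clean_frame):
        table = collecting_effort(clean_frame, "genus").set_index("taxon")
        for genus, sub in clean_frame.groupby("genus"):
            assert table.loc[genus, "n_species"] == sub["scientificName"].nunique()
            assert table.loc[genus, "n_records"] == len(sub)
            assert table.loc[genus, "effort"] == pytest.approx(
                math.log10(len(sub) / sub["scientificName"].nunique())
            )


class TestEffortFamilyContrast:
    def effort_table(self, efforts):
        return pd.DataFrame(
            {
                "taxon": [f"F{i}" for i in range(len(efforts))],
                "n_species": np.arange(len(efforts), 0, -1) * 10,
                "n_records": 100,
                "effort": efforts,
            }
        )

    def test_singleton_focal_group_flagged(self):
        table = self.effort_table([1.0, 1.5, 2.0, 2.5])
        res = effort_family_contrast(table, "F0", k=3)
        assert res.group_sizes == [1, 3]
        assert res.note is not None and "singleton" in res.note

    def test_group_means_equal_ledgered_efforts(self):
        efforts = [0.5, 1.0, 2.0, 3.0, 4.0]
        res = effort_family_contrast(self.effort_table(efforts), "F0", k=4)
        assert res.group_means[0] == pytest.approx(0.5)
        assert res.group_means[1] == pytest.approx(np.mean(efforts[1:]))

    def test_focal_far_below_comparison_gives_small_p(self):
        rng = np.random.default_rng(6)
        efforts = [0.1] + list(rng.normal(2.0, 0.1, size=10))
        res = effort_family_contrast(self.effort_table(efforts), "F0", k=10)
        assert res.p_value < 0.001

    def test_zero_comparison_variance_degenerate(self):
        res = effort_family_contrast(self.effort_table([2.0, 2.0, 2.0, 2.0]), "F0", k=3)
        assert res.f_stat == 0.0 and res.p_value == 1.0  # no effect, no variance


class TestDiversityVsArea:
    def table(self):
        return pd.DataFrame(
            {
                "region": ["Australia", "B", "C", "D", "E"],
                "n_species": [100, 200, 300, 150, 50],
                "area_km2": [1e6, 2e6, 3e6, 1.5e6, 0.5e6],
            }
        )

    def test_equal_densities_give_f_near_zero(self):
        res = diversity_vs_area(self.table(), "Australia")
        assert res["all"].density_anova.f_stat == pytest.approx(0.0, abs=1e-18)

    def test_regression_matches_oracle_on_log10(self):
        table = self.table()
        res = diversity_vs_area(table, "Australia")
        oracle = linear_regression(
            table["area_km2"].to_numpy(),
            np.log10(table["n_species"].to_numpy()),
        )
        assert res["all"].regression.r_squared == pytest.approx(oracle.r_squared)

    def test_excluding_region_drops_df_by_one(self):
        res = diversity_vs_area(self.table(), "Australia", excluded_region="E")
        d_all = res["all"].density_anova
        d_exc = res["excluded"].density_anova
        assert d_all.df_within - d_exc.df_within == 1
        assert res["excluded"].regression.df[1] == res["all"].regression.df[1] - 1

    def test_zero_area_rejected(self):
        table = self.table()
        table.loc[0, "area_km2"] = 0.0
        with pytest.raises(InputError):
            diversity_vs_area(table, "Australia")
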