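"""Descriptives, rank/contingency tests, dichotomization, ANCOVA ladder."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rwahome.stats import (
    MODEL_COVARIATES,
    contingency_2x2,
    describe,
    dichotomize,
    fit_ancova,
    holm_adjust,
    build_tables,
    mann_whitney,
    mann_whitney_exact_enumeration,
)
from rwahome.synth import CohortSpec, simulate_cohort


class TestDescribe:
    def test_probable_rbd_group_summaries(self, table4_groups):
        c, _ = table4_groups
        d = describe(c)
        assert round(d.mean, 1) == 17.7
        assert round(d.median, 1) == 17.4
        assert round(d.sem, 1) == 3.1
        assert (round(d.min, 1), round(d.max, 1)) == (1.2, 39.1)

    def test_without_probable_rbd_group_summaries(self, table4_groups):
        _, b = table4_groups
        d = describe(b)
        assert round(d.mean, 1) == 27.0
        assert round(d.median, 1) == 20.6
        assert round(d.sem, 1) == 7.6
        assert (round(d.min, 1), round(d.max, 1)) == (4.4, 84.3)

    def test_single_value_dispersion_undefined(self):
        d = describe([5.0])
        assert d.mean == d.median == 5.0
        assert np.isnan(d.sd) and np.isnan(d.sem)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            describe([])


class TestMannWhitney:
    def test_tiny_exact_case_against_hand_enumeration(self):
        # x={1,2}, y={3,4}: U=0; of C(4,2)=6 assignments, 2 are as extreme
        res = mann_whitney([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.u == 0.0
        assert res.p == pytest.approx(1 / 3)

    def test_identical_samples_with_ties_are_null(self):
        x = [1.0, 2.0, 2.0, 3.0]
        res = mann_whitney(x, x)
        assert res.method == "asymptotic"
        assert res.p == pytest.approx(1.0, abs=0.05)
        assert res.r == pytest.approx(0.0, abs=0.01)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n1, n2 = rng.integers(2, 5, 2)
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1) * 1.37)
            x, y = pooled[:n1], pooled[n1:]
            assert mann_whitney(x, y).p == pytest.approx(
                mann_whitney_exact_enumeration(x, y), abs=1e-12
            )

    def test_large_or_tied_samples_fall_back_to_asymptotic(self):
        rng = np.random.default_rng(0)
        res = mann_whitney(rng.normal(size=20), rng.normal(size=20))
        assert res.method == "asymptotic"
        assert 0 <= res.p <= 1

    def test_exact_refused_with_ties(self):
        with pytest.raises(ValueError, match="ties"):
            mann_whitney([1, 1], [2, 3], method="exact")

    def test_effect_size_consistent_with_z(self):
        res = mann_whitney(np.arange(10.0), np.arange(10.0) + 5.3)
        assert res.r == pytest.approx(abs(res.z) / np.sqrt(20))


class TestContingency:
    def test_sex_table_phi(self):
        res = contingency_2x2(18, 9, 7, 7)
        assert round(res.phi, 3) == 0.162
        assert round(res.p, 3) == 0.332  # Fisher two-sided

    def test_rbdsq_table_phi(self):
        res = contingency_2x2(15, 12, 8, 6)
        assert round(res.phi, 3) == 0.015
        assert res.p > 0.999

    def test_perfect_association(self):
        assert contingency_2x2(10, 0, 0, 10).phi == pytest.approx(1.0)

    def test_zero_margin_undefined(self):
        with pytest.raises(ValueError, match="margin"):
            contingency_2x2(5, 5, 0, 0)

    def test_pearson_option(self):
        res = contingency_2x2(20, 10, 8, 15, method="chi2")
        assert res.method == "chi2" and 0 <= res.p <= 1

    @given(
        a=st.integers(1, 30), b=st.integers(1, 30),
        c=st.integers(1, 30), d=st.integers(1, 30),
    )
    @settings(max_examples=60, derandomize=True)
    def test_phi_symmetry(self, a, b, c, d):
        """phi is invariant to transposition and row/column swaps."""
        base = contingency_2x2(a, b, c, d).phi
        assert contingency_2x2(a, c, b, d).phi == pytest.approx(base)  # transpose
        assert contingency_2x2(c, d, a, b).phi == pytest.approx(base)  # row swap
        assert contingency_2x2(b, a, d, c).phi == pytest.approx(base)  # col swap


class TestDichotomize:
    @pytest.mark.parametrize(
        "col,field,value,expected",
        [
            ("leed", "leed_ge_400", 400.0, 1.0),  # inclusive
            ("leed", "leed_ge_400", 399.9, 0.0),
            ("disease_duration", "duration_gt_109", 109.0, 0.0),  # strict
            ("disease_duration", "duration_gt_109", 109.1, 1.0),
            ("bdi", "depression", 14, 1.0),
            ("bdi", "depression", 13, 0.0),
            ("pfs", "fatigue", 3.3, 1.0),
            ("anxiety", "anxiety_ge_2", 2, 1.0),
            ("psychosis", "psychosis_ge_2", 1.5, 0.0),
            ("rbdsq", "rbdsq_ge_5", 5, 1.0),
        ],
    )
    def test_cutoff_boundary_semantics(self, col, field, value, expected):
        rec = pd.DataFrame([{col: value, "sex": "M"}])
        assert dichotomize(rec)[field].iloc[0] == expected

    def test_missing_field_is_nan_not_zero(self):
        out = dichotomize(pd.DataFrame([{"sex": "F", "age": 70.0}]))
        assert np.isnan(out["leed_ge_400"].iloc[0])
        assert np.isnan(out["depression"].iloc[0])
        assert out["male"].iloc[0] == 0.0

    def test_log_terms(self):
        rec = pd.DataFrame([{"updrs3": 20.0, "pdss2_nocturnal": 5.0, "sex": "M"}])
        out = dichotomize(rec)
        assert out["log_updrs3"].iloc[0] == pytest.approx(np.log(20.0))
        assert out["log_pdss_nocturnal"].iloc[0] == pytest.approx(np.log(5.0))

    def test_nonpositive_log_source_warns_and_nans(self):
        rec = pd.DataFrame([{"updrs3": 0.0, "sex": "M"}])
        with pytest.warns(UserWarning, match="non-positive"):
            out = dichotomize(rec)
        assert np.isnan(out["log_updrs3"].iloc[0])


class TestAncova:
    def test_unadjusted_model_equals_group_mean_difference(self):
        df = simulate_cohort(CohortSpec(n_patients=120, seed=5))
        res = fit_ancova(df, "none")
        expected = (
            df.loc[df.rwa_positive, "log_rem"].mean()
            - df.loc[~df.rwa_positive, "log_rem"].mean()
        )
        assert res.difference == pytest.approx(expected, abs=1e-10)
        assert res.ratio == pytest.approx(np.exp(expected))

    def test_orthogonal_covariate_leaves_group_coefficient_unchanged(self):
        rng = np.random.default_rng(2)
        n = 80
        g = np.repeat([0.0, 1.0], n // 2)
        y = 1.0 + 0.8 * g + rng.normal(0, 0.5, n)
        cov = np.tile([-1.0, 1.0], n // 2)  # balanced within both groups
        cov = cov - cov.mean()
        df = pd.DataFrame({"rwa_positive": g.astype(bool), "log_rem": y, "age": cov, "sex": "M"})
        df["bmi"] = 22.0 + np.tile([-1.0, 1.0, 1.0, -1.0], n // 4)
        base = fit_ancova(df, "none")
        # a model using only the orthogonal covariates: age (balanced) only
        design = pd.concat(
            [df[["rwa_positive", "log_rem"]], pd.DataFrame({"age": cov})], axis=1
        )
        import statsmodels.api as sm

        X = sm.add_constant(pd.DataFrame({"rwa": g, "age": cov}))
        fit = sm.OLS(y, X).fit()
        assert fit.params["rwa"] == pytest.approx(base.difference, abs=1e-10)

    def test_ci_brackets_estimate_and_ratio_is_exp(self):
        df = simulate_cohort(CohortSpec(n_patients=200, seed=8))
        for mid in (1, 2, 3, "full"):
            r = fit_ancova(df, mid)
            assert r.ci_low <= r.difference <= r.ci_high
            assert r.ratio == pytest.approx(np.exp(r.difference))
            assert r.ratio_ci_low == pytest.approx(np.exp(r.ci_low))
            assert 0 <= r.p <= 1 and 0 <= r.effect_size <= 1

    def test_rank_deficient_design_names_collinear_columns(self):
        df = simulate_cohort(CohortSpec(n_patients=60, seed=1)).copy()
        df["bmi"] = df["age"] * 2.0  # exact collinearity
        with pytest.raises(ValueError, match="collinear.*age|age.*collinear"):
            fit_ancova(df, 1)

    def test_too_few_cases_rejected(self):
        df = simulate_cohort(CohortSpec(n_patients=10, seed=2))
        with pytest.raises(ValueError, match="too few"):
            fit_ancova(df, "full")

    def test_model_ladder_is_nested(self):
        assert set(MODEL_COVARIATES[1]) < set(MODEL_COVARIATES[2])
        assert set(MODEL_COVARIATES[2]) < set(MODEL_COVARIATES[3])
        assert set(MODEL_COVARIATES[3]) < set(MODEL_COVARIATES["full"])


class TestTables:
    def test_synthetic_cohort_fills_every_cell(self):
        df = simulate_cohort(CohortSpec(n_patients=120, seed=6))
        tabs = build_tables(df)
        t1 = tabs["table1"]
        assert t1["computable"].all()
        assert t1["p"].between(0, 1).all()
        assert not tabs["table2"]["difference"].isna().any()
        assert set(tabs["table3"].attrs["group_sizes"]) == {"A", "B", "C"}

    def test_single_group_cohort_marks_not_computable(self):
        df = simulate_cohort(CohortSpec(n_patients=40, p_rwa=1.0, seed=3))
        t1 = build_tables(df)["table1"]
        assert not t1["computable"].any()

    def test_table4_fixture_three_group_sizes(self, table4):
        df = table4.rename(columns={"patient_id": "pid"}).copy()
        df["rwa_positive"] = True
        df["sex"] = "M"
        tabs = build_tables(df)
        sizes = tabs["table3"].attrs["group_sizes"]
        assert sizes["C"] == 15 and sizes["B"] == 10

    def test_holm_adjustment_is_monotone_and_bounded(self):
        p = pd.Series([0.001, 0.04, 0.03, 0.2, np.nan])
        adj = holm_adjust(p)
        assert (adj.dropna() >= p.dropna() - 1e-15).all()
        assert (adj.dropna() <= 1.0).all()
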