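"""Epidemiological-layer tests: classification, HOMA-IR, tertiles, model ladder,
splines, and the attenuation decompositions."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

import admixscan as ax
from admixscan import tables
from admixscan.epi import rcs_knots
from admixscan.errors import DecompositionError


class TestClassification:
    @pytest.mark.parametrize(
        "record,status",
        [
            ({"glucose": 126.0, "fasting": 1}, "case"),
            ({"glucose": 125.9, "fasting": 1}, "control"),
            ({"glucose": 199.0, "fasting": 0}, "control"),
            ({"glucose": 200.0, "fasting": 0}, "case"),
            ({"hba1c": 6.5}, "case"),
            ({"hba1c": 6.4}, "control"),
            ({"on_treatment": 1}, "case"),
            ({"self_report": 1}, "case"),
            ({"on_treatment": 1, "age_at_diagnosis": 29, "study": "ARIC"}, "excluded"),
            ({"on_treatment": 1, "age_at_diagnosis": 30, "study": "ARIC"}, "case"),
            ({"on_treatment": 1, "age_at_diagnosis": 29, "study": "MEC"}, "case"),
        ],
    )
    def test_diagnostic_rules(self, record, status):
        assert ax.classify_diabetes(record)[0] == status

    def test_glucose_without_fasting_flag_is_flagged(self):
        status, flagged = ax.classify_diabetes({"glucose": 150.0})
        assert status == "control" and flagged
        status, flagged = ax.classify_diabetes({"glucose": 210.0})
        assert status == "case" and flagged

    def test_vectorised_classification_matches_scalar(self, small_sim):
        out = ax.classify_cohort(small_sim.cohort)
        assert set(out["dm_status"]) <= {"case", "control", "excluded"}
        row = small_sim.cohort.iloc[0]
        assert out["dm_status"].iloc[0] == ax.classify_diabetes(row)[0]


class TestHomaIr:
    def test_unit_conversion_matches_diagnostic_cut(self):
        # 126 mg/dL is the same glucose as 7.0 mmol/L.
        assert abs(ax.homa_ir(126.0, 10.0, "mg/dL") - ax.homa_ir(7.0, 10.0)) < 1e-12

    def test_constant_cancels(self):
        assert ax.homa_ir(22.5, 1.0) == 1.0

    def test_arithmetic(self):
        assert abs(ax.homa_ir(5.0, 9.0) - 2.0) < 1e-12

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ax.homa_ir(0.0, 5.0)
        with pytest.raises(ValueError):
            ax.homa_ir(5.0, 5.0, "mol/L")


class TestTertiles:
    def test_uniform_sample_cuts(self, rng):
        t = ax.ancestry_tertiles(rng.uniform(0, 1, 3000))
        assert abs(t.cuts[0] - 1 / 3) < 0.02 and abs(t.cuts[1] - 2 / 3) < 0.02
        assert set(t.labels) == {1, 2, 3}

    def test_three_point_distribution(self):
        t = ax.ancestry_tertiles([0.1] * 10 + [0.5] * 10 + [0.9] * 10)
        assert (t.labels[:10] == 1).all() and (t.labels[10:20] == 2).all() and (
            t.labels[20:] == 3
        ).all()

    def test_ties_go_to_lower_tertile(self):
        t = ax.ancestry_tertiles(np.arange(9, dtype=float))
        cut = t.cuts[0]
        assert t.labels[np.flatnonzero(np.arange(9) == np.floor(cut))[-1]] == 1

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(DecompositionError):
            ax.ancestry_tertiles([0.5, 0.5, 0.5])


class TestDecompositionFormulas:
    @pytest.mark.parametrize(
        "theta1,theta2,expected",
        [(1.48, 1.40, 16.7), (1.35, 1.26, 25.7), (1.25, 1.21, 16.0), (1.47, 1.33, 29.8)],
    )
    def test_excess_odds_examples(self, theta1, theta2, expected):
        assert round(ax.excess_odds_explained(theta1, theta2), 1) == expected

    @pytest.mark.parametrize(
        "beta1,beta2,expected", [(0.10, 0.06, 40.0), (0.68, 0.23, 66.2), (0.23, 0.07, 69.6)]
    )
    def test_effect_explained_examples(self, beta1, beta2, expected):
        assert round(ax.effect_explained(beta1, beta2), 1) == expected

    def test_no_attenuation_is_zero(self):
        assert ax.excess_odds_explained(1.5, 1.5) == 0.0
        assert ax.effect_explained(0.4, 0.4) == 0.0

    def test_undefined_decompositions(self):
        with pytest.raises(DecompositionError):
            ax.excess_odds_explained(0.9, 0.8)
        with pytest.raises(DecompositionError):
            ax.effect_explained(0.0, 0.1)

    @settings(derandomize=True, max_examples=50)
    @given(
        excess=st.floats(0.05, 5), ratio=st.floats(-1, 1), c=st.floats(0.1, 10)
    )
    def test_excess_odds_scale_free(self, excess, ratio, c):
        t1, t2 = 1 + excess, 1 + excess * ratio
        s1, s2 = 1 + c * excess, 1 + c * excess * ratio
        assert ax.excess_odds_explained(t1, t2) == pytest.approx(
            ax.excess_odds_explained(s1, s2), abs=1e-8
        )

    @settings(derandomize=True, max_examples=50)
    @given(b1=st.floats(0.01, 10), ratio=st.floats(-2, 2), c=st.floats(0.1, 10))
    def test_effect_explained_scale_free(self, b1, ratio, c):
        assert ax.effect_explained(b1, b1 * ratio) == pytest.approx(
            ax.effect_explained(c * b1, c * b1 * ratio), abs=1e-8
        )


class TestPrintedTables:
    def test_unadjusted_or_matches_independent_logistic_fit(self):
        """The cross-product OR from printed counts equals a fitted 2x2 logit."""
        counts = tables.TABLE2_ODDS_RATIOS["ARIC+JHS+MEC"]["counts"]
        y, x = [], []
        for tert, (cases, controls) in ((1, counts[1]), (3, counts[3])):
            y += [1] * cases + [0] * controls
            x += [int(tert == 3)] * (cases + controls)
        fit = sm.GLM(np.array(y), sm.add_constant(np.array(x, dtype=float)),
                     family=sm.families.Binomial()).fit()
        assert np.exp(fit.params[1]) == pytest.approx(tables.unadjusted_tertile_or(3), abs=1e-6)

    def test_recomputed_tables_are_complete(self):
        t2 = tables.recompute_excess_odds_table()
        t3 = tables.recompute_effect_explained_table()
        assert len(t2) == 1 * 2 + 3 * 2  # combined: 1 adjusted model; two-cohort: 3
        assert len(t3) == 4 * 3 * 2  # 4 traits x 3 adjusted models x 2 tertiles


def synthetic_tertile_cohort(n, log_or_t2, log_or_t3, seed):
    rng = np.random.default_rng(seed)
    anc = rng.uniform(0, 1, n)
    t = ax.ancestry_tertiles(anc)
    age = rng.uniform(45, 75, n)
    sex = rng.choice(["M", "F"], n)
    study = rng.choice(["ARIC", "JHS"], n)
    logit = -0.8 + log_or_t2 * (t.labels == 2) + log_or_t3 * (t.labels == 3) + 0.02 * (age - 55)
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(int)
    return pd.DataFrame(
        {"diabetes": y, "african_ancestry": anc, "age": age, "sex": sex,
         "study": study, "bmi": rng.normal(28, 4, n)}
    )


class TestModelLadder:
    def test_known_tertile_log_odds_recovered(self):
        df = synthetic_tertile_cohort(7000, np.log(1.5), np.log(2.0), seed=2)
        res = ax.fit_logistic_tertiles(df, models=(1, 2))
        m1 = res[res.model_id == 1].set_index("tertile")
        for tert, target in ((2, np.log(1.5)), (3, np.log(2.0))):
            beta = m1.loc[tert, "beta"]
            se = (np.log(m1.loc[tert, "ci_high"]) - np.log(m1.loc[tert, "ci_low"])) / (2 * 1.96)
            assert abs(beta - target) <= 2 * se
        assert (res[res.model_id == 1]["trend_p"] < 1e-6).all()

    def test_null_cohort_gives_unit_odds_ratios(self):
        df = synthetic_tertile_cohort(6000, 0.0, 0.0, seed=3)
        res = ax.fit_logistic_tertiles(df, models=(1,))
        for row in res.itertuples():
            se = (np.log(row.ci_high) - np.log(row.ci_low)) / (2 * 1.96)
            assert abs(row.beta) <= 4 * se

    def test_percent_explained_consistent_with_formula(self, small_sim):
        df = small_sim.cohort.copy()
        df["african_ancestry"] = df["true_ancestry"]
        res = ax.fit_logistic_tertiles(df, models=(1, 2))
        base = res[res.model_id == 1].set_index("tertile")["estimate"]
        for row in res[res.model_id == 2].itertuples():
            if base[row.tertile] > 1:
                assert row.percent_explained == pytest.approx(
                    ax.excess_odds_explained(base[row.tertile], row.estimate)
                )

    def test_trait_ladder_null_effect(self):
        rng = np.random.default_rng(4)
        n = 4000
        df = pd.DataFrame(
            {"african_ancestry": rng.uniform(0, 1, n), "age": rng.uniform(45, 75, n),
             "sex": rng.choice(["M", "F"], n), "study": rng.choice(["ARIC", "JHS"], n),
             "bmi": rng.normal(28, 4, n), "hba1c": rng.normal(5.6, 0.6, n),
             "on_treatment": 0}
        )
        res = ax.fit_trait_models(df, "hba1c", models=(1,))
        for row in res.itertuples():
            assert abs(row.estimate) <= 4 * (row.ci_high - row.ci_low) / (2 * 1.96)

    def test_trait_percent_explained_internal_consistency(self, small_sim):
        df = small_sim.cohort[small_sim.cohort.study != "MEC"].copy()
        df["african_ancestry"] = df["true_ancestry"]
        res = ax.fit_trait_models(df, "hba1c", models=(1, 2), exclude_treated=True)
        base = res[res.model_id == 1].set_index("tertile")["beta"]
        for row in res[res.model_id == 2].itertuples():
            assert row.percent_explained == pytest.approx(
                ax.effect_explained(float(base[row.tertile]), row.beta)
            )

    def test_exclude_treated_shrinks_sample(self, small_sim):
        df = small_sim.cohort[small_sim.cohort.study != "MEC"].copy()
        df["african_ancestry"] = df["true_ancestry"]
        with_excl = ax.fit_trait_models(df, "hba1c", models=(1,), exclude_treated=True)
        without = ax.fit_trait_models(df, "hba1c", models=(1,), exclude_treated=False)
        if (df["on_treatment"] == 1).any():
            assert with_excl.attrs["n"] < without.attrs["n"]

    def test_variance_explained_recovery(self):
        """Incremental R^2 of a known-effect covariate recovered within 0.3pp."""
        rng = np.random.default_rng(9)
        n = 5000
        z = rng.standard_normal(n)
        b, sigma = 0.3, 1.0
        y = b * z + rng.normal(0, sigma, n)
        # Oracle: the realized squared correlation between y and z.
        target = 100 * np.corrcoef(y, z)[0, 1] ** 2
        df = pd.DataFrame(
            {"y": y, "z": z,
             "age": rng.uniform(45, 75, n), "sex": rng.choice(["M", "F"], n),
             "study": rng.choice(["ARIC", "JHS"], n)}
        )
        got = ax.variance_explained(df, "y", "z")
        assert abs(got - target) <= 0.3

    def test_noise_covariate_barely_moves_percent_explained(self):
        """Adding an independent covariate shifts percent explained by < 2 points."""
        df = synthetic_tertile_cohort(6000, np.log(1.4), np.log(1.8), seed=12)
        rng = np.random.default_rng(13)
        res = ax.fit_logistic_tertiles(df, models=(1, 2))
        df2 = df.copy()
        df2["bmi"] = rng.normal(28, 4, len(df))  # replace with pure noise
        res2 = ax.fit_logistic_tertiles(df2, models=(1, 2))
        for (r1, r2) in zip(
            res[res.model_id == 2].itertuples(), res2[res2.model_id == 2].itertuples()
        ):
            assert abs(r1.percent_explained - r2.percent_explained) < 2.0


class TestSplines:
    def test_four_knots_give_three_columns(self, rng):
        x = rng.uniform(0, 1, 200)
        basis = ax.rcs_basis(x, [0.1, 0.35, 0.65, 0.9])
        assert basis.shape == (200, 3)

    def test_linear_beyond_boundary_knots(self):
        knots = np.array([0.1, 0.35, 0.65, 0.9])
        for x0 in (0.95, 1.3, 0.05):
            h = 1e-3
            x = np.array([x0 - h, x0, x0 + h])
            basis = ax.rcs_basis(x, knots)
            second = basis[0] - 2 * basis[1] + basis[2]
            if x0 > knots[-1] or x0 < knots[0]:
                np.testing.assert_allclose(second, 0.0, atol=1e-9)

    def test_duplicate_or_too_few_knots_rejected(self):
        with pytest.raises(ValueError):
            ax.rcs_basis(np.linspace(0, 1, 10), [0.2, 0.2, 0.6, 0.9])
        with pytest.raises(ValueError):
            ax.rcs_basis(np.linspace(0, 1, 10), [0.2, 0.5, 0.8])

    def test_basis_spans_constrained_truncated_power_space(self, rng):
        """Each nonlinear column is a combination of (x-t_j)+^3 whose cubic and
        quadratic tail terms vanish (the natural-spline constraints)."""
        knots = np.array([0.1, 0.35, 0.65, 0.9])
        x = np.sort(rng.uniform(-0.2, 1.2, 400))
        basis = ax.rcs_basis(x, knots)
        P = np.clip(x[:, None] - knots[None, :], 0, None) ** 3  # raw truncated cubics
        for j in (1, 2):
            c, res, *_ = np.linalg.lstsq(P, basis[:, j], rcond=None)
            assert np.sqrt(res[0] if len(res) else 0.0) < 1e-8
            assert abs(c.sum()) < 1e-8  # cubic tail cancels
            assert abs((c * knots).sum()) < 1e-8  # quadratic tail cancels

    def test_linear_data_needs_no_nonlinear_terms(self, rng):
        x = rng.uniform(0, 1, 500)
        y = 2.0 + 3.0 * x
        basis = ax.rcs_basis(x, rcs_knots(x))
        fit = sm.OLS(y, sm.add_constant(basis)).fit()
        np.testing.assert_allclose(fit.params[2:], 0.0, atol=1e-6)
        assert fit.params[1] == pytest.approx(3.0, abs=1e-6)

    def test_risk_curve_reference_is_unity(self, small_sim):
        df = small_sim.cohort.copy()
        df["african_ancestry"] = df["true_ancestry"]
        x = df["african_ancestry"].to_numpy()
        ref = np.percentile(x, 5)
        curve = ax.rcs_logistic_curve(df, grid=np.array([ref, 0.5, 0.9]))
        assert curve["odds_ratio"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert np.isfinite(curve[["odds_ratio", "ci_low", "ci_high"]].to_numpy()).all()
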