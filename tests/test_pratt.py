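"""Within/between covariance decomposition, level models and Pratt indices."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mealvar import (
    SimulationConfig,
    ValidationError,
    compute_prior_interval,
    decompose_two_level,
    exclude_zeros_log,
    fit_meal_models,
    level_model,
    pratt_index,
    select_meals,
    simulate_intake,
    simulate_participants,
)
from mealvar.errors import EstimationError


def _cov_frame(matrix, names):
    return pd.DataFrame(matrix, index=names, columns=names)


class TestDecomposition:
    def test_balanced_two_by_two_scaling_constant(self):
        z = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0]})
        dec = decompose_two_level(z, ["a", "a", "b", "b"])
        assert dec.c == pytest.approx(2.0)

    def test_unbalanced_scaling_constant(self):
        z = pd.DataFrame({"y": np.arange(5.0)})
        dec = decompose_two_level(z, ["a", "a", "b", "b", "b"])
        assert dec.c == pytest.approx((5 - 13 / 5) / 1)  # 2.4

    def test_hand_computed_within_and_between_sums(self):
        # 2 clusters x 2 rows with integer values; S_PW and S_B by hand:
        # cluster a: y (1,3) x (2,6); cluster b: y (5,9) x (4,8)
        z = pd.DataFrame({"y": [1.0, 3.0, 5.0, 9.0], "x": [2.0, 6.0, 4.0, 8.0]})
        dec = decompose_two_level(z, ["a", "a", "b", "b"])
        # within deviations: a: (-1,1) & (-2,2); b: (-2,2) & (-2,2); N-G = 2
        s_pw = np.array([[(1 + 1 + 4 + 4) / 2, (2 + 2 + 4 + 4) / 2],
                         [(2 + 2 + 4 + 4) / 2, (4 + 4 + 4 + 4) / 2]])
        assert np.allclose(dec.s_pw.to_numpy(), s_pw)
        # cluster means: a (2,4), b (7,6); grand (4.5, 5); G-1 = 1
        s_b = np.array([[2 * 2.5**2 + 2 * 2.5**2, 2 * 2.5 + 2 * 2.5 * 1.0],
                        [2 * 2.5 + 2 * 2.5, 2 * 1.0 + 2 * 1.0]])
        assert np.allclose(dec.s_b.to_numpy(), s_b)
        # x's between variance is negative here (4 - 8)/2 -> floored at 0
        expected_sigma_b = (s_b - s_pw) / dec.c
        expected_sigma_b[1, 1] = 0.0
        assert np.allclose(dec.sigma_b.to_numpy(), expected_sigma_b, atol=1e-12)
        assert dec.floored == ("x",)

    def test_between_only_variable_has_zero_within_rows(self):
        z = pd.DataFrame({"y": [1.0, 2.0, 5.0, 7.0], "w": [3.0, 3.0, 8.0, 8.0]})
        dec = decompose_two_level(z, ["a", "a", "b", "b"])
        assert dec.s_pw.loc["w", "w"] == 0.0
        assert dec.s_pw.loc["w", "y"] == 0.0

    def test_negative_between_diagonal_floored_and_flagged(self):
        # within variance large, cluster means identical -> Sigma_B diag < 0
        z = pd.DataFrame({"y": [0.0, 10.0, 5.0, 0.0, 10.0, 5.0]})
        dec = decompose_two_level(z, ["a", "a", "a", "b", "b", "b"])
        assert dec.sigma_b.loc["y", "y"] == 0.0
        assert "y" in dec.floored

    def test_single_cluster_rejected(self):
        z = pd.DataFrame({"y": [1.0, 2.0]})
        with pytest.raises(ValidationError):
            decompose_two_level(z, ["a", "a"])

    def test_all_singleton_clusters_rejected(self):
        z = pd.DataFrame({"y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError):
            decompose_two_level(z, ["a", "b", "c"])


class TestLevelModel:
    def test_single_predictor_beta_equals_correlation(self):
        sigma = _cov_frame([[4.0, 1.0], [1.0, 1.0]], ["y", "x"])
        beta, r, r2 = level_model(sigma, "y", ["x"])
        assert beta["x"] == pytest.approx(r["x"])
        assert r2 == pytest.approx(r["x"] ** 2)

    def test_two_predictor_normal_equations_by_hand(self):
        # r_x1y = .5, r_x2y = .3, r_x1x2 = .2 -> beta = (.45833, .20833)
        sigma = _cov_frame(
            [[1.0, 0.5, 0.3], [0.5, 1.0, 0.2], [0.3, 0.2, 1.0]], ["y", "x1", "x2"]
        )
        beta, r, r2 = level_model(sigma, "y", ["x1", "x2"])
        assert beta["x1"] == pytest.approx(0.5 - 0.2 * (0.3 - 0.1) / 0.96, abs=1e-10)
        assert beta.to_numpy() == pytest.approx([0.44 / 0.96, 0.20 / 0.96], abs=1e-10)
        assert r2 == pytest.approx(0.44 / 0.96 * 0.5 + 0.20 / 0.96 * 0.3, abs=1e-10)
        pi = pratt_index(beta, r, r2)
        assert pi.to_numpy() == pytest.approx([0.785714285714, 0.214285714286], abs=1e-10)

    def test_orthogonal_predictors_betas_equal_correlations(self):
        sigma = _cov_frame(
            [[1.0, 0.5, 0.3], [0.5, 1.0, 0.0], [0.3, 0.0, 1.0]], ["y", "x1", "x2"]
        )
        beta, r, r2 = level_model(sigma, "y", ["x1", "x2"])
        assert np.allclose(beta.to_numpy(), r.to_numpy())
        assert r2 == pytest.approx(0.25 + 0.09)

    def test_collinear_predictors_named(self):
        sigma = _cov_frame(
            [[1.0, 0.5, 0.5], [0.5, 1.0, 1.0], [0.5, 1.0, 1.0]], ["y", "x1", "x2"]
        )
        with pytest.raises(EstimationError, match="x1 ~ x2"):
            level_model(sigma, "y", ["x1", "x2"])


class TestPrattIndex:
    def test_single_predictor_index_is_one(self):
        beta = pd.Series({"x": 0.4})
        r = pd.Series({"x": 0.4})
        assert pratt_index(beta, r, 0.16)["x"] == pytest.approx(1.0)

    def test_zero_beta_gives_zero_index(self):
        beta = pd.Series({"x1": 0.5, "x2": 0.0})
        r = pd.Series({"x1": 0.5, "x2": 0.2})
        pi = pratt_index(beta, r, 0.25)
        assert pi["x2"] == 0.0

    def test_zero_r2_rejected(self):
        with pytest.raises(EstimationError):
            pratt_index(pd.Series({"x": 0.0}), pd.Series({"x": 0.0}), 0.0)


@st.composite
def random_covariance(draw):
    """Random PSD covariance over y + 2..4 predictors via a factor loading."""
    k = draw(st.integers(min_value=3, max_value=5))
    rows = draw(
        st.lists(
            st.lists(
                st.floats(min_value=-2.0, max_value=2.0, allow_nan=False),
                min_size=k + 1, max_size=k + 1,
            ),
            min_size=k, max_size=k,
        )
    )
    a = np.array(rows)
    sigma = a @ a.T + 0.5 * np.eye(k)
    names = ["y"] + [f"x{j}" for j in range(1, k)]
    return _cov_frame(sigma, names)


class TestPrattProperties:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(random_covariance())
    def test_additivity_and_scale_invariance(self, sigma):
        names = list(sigma.columns)
        preds = names[1:]
        beta, r, r2 = level_model(sigma, "y", preds)
        if abs(r2) <= 1e-8:
            return
        pi = pratt_index(beta, r, r2)
        assert pi.sum() == pytest.approx(1.0, abs=1e-8)
        # rescale y and one predictor by positive constants
        scale = pd.Series(1.0, index=names)
        scale["y"] = 7.3
        scale[preds[0]] = 0.04
        scaled = sigma * np.outer(scale, scale)
        beta2, r2_, rr2 = level_model(scaled, "y", preds)
        assert np.allclose(beta.to_numpy(), beta2.to_numpy(), atol=1e-10)
        assert np.allclose(r.to_numpy(), r2_.to_numpy(), atol=1e-10)
        assert rr2 == pytest.approx(r2, abs=1e-10)
        assert np.allclose(pi.to_numpy(), pratt_index(beta2, r2_, rr2).to_numpy(), atol=1e-10)


def _simulate_prepared(config):
    participants = simulate_participants(config)
    table = simulate_intake(participants, config)
    table = compute_prior_interval(table, occasion_order=None)
    table = select_meals(table)
    table, _ = exclude_zeros_log(table, "energy")
    return participants, table


class TestFitMealModels:
    def test_null_within_effect_yields_negligible_r2(self):
        cfg = SimulationConfig(
            n_participants=400, beta_within={"special_day": 0.0}, beta_between={},
            meal_attendance=1.0, snack_rate=0.0, missing_meal_rate=0.0,
            include_tee=False, zero_rate=0.0, seed=31,
        )
        participants, table = _simulate_prepared(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = fit_meal_models(
                table, participants, "energy", ("special_day",), ("sex",),
                meals=("lunch",), min_r2=0.05,
            )
        within = [r for r in results if r.level == "within"][0]
        assert within.r2 < 0.05
        assert not within.pratt_valid and within.pratt is None

    def test_within_model_matches_centered_ols_oracle(self):
        """With no participant-level variance, the within result equals an
        ordinary regression Pratt computation on cluster-mean-centered data."""
        cfg = SimulationConfig(
            n_participants=150, var_participant=0.0, var_mealcell=0.0,
            var_occasion=0.4,
            beta_within={"special_day": 0.3, "weekend": 0.15}, beta_between={},
            meal_attendance=1.0, snack_rate=0.0, missing_meal_rate=0.0,
            include_tee=False, zero_rate=0.0, seed=33,
        )
        participants, table = _simulate_prepared(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_meal_models(
                table, participants, "energy", ("special_day", "weekend"), ("sex",),
                meals=("dinner",),
            )
        within = [r for r in res if r.level == "within"][0]

        sub = table[table["meal_type"] == "dinner"].copy()
        sub["sd"] = (sub["special_day"] == "y").astype(float)
        sub["we"] = (sub["weekend"] == "y").astype(float)
        cols = ["log_energy", "sd", "we"]
        centered = sub[cols] - sub.groupby("participant_id")[cols].transform("mean")
        G = sub["participant_id"].nunique()
        n = len(sub)
        cov = centered.cov(ddof=0) * n / (n - G)  # pooled within, N-G dof
        xx = cov.loc[["sd", "we"], ["sd", "we"]].to_numpy()
        xy = cov.loc[["sd", "we"], "log_energy"].to_numpy()
        b = np.linalg.solve(xx, xy)
        sds = np.sqrt(np.diag(xx))
        sy = np.sqrt(cov.loc["log_energy", "log_energy"])
        beta = b * sds / sy
        r = xy / (sds * sy)
        r2 = float(beta @ r)
        assert within.beta.to_numpy() == pytest.approx(beta, abs=1e-8)
        assert within.r.to_numpy() == pytest.approx(r, abs=1e-8)
        assert within.r2 == pytest.approx(r2, abs=1e-8)
        assert within.pratt.to_numpy() == pytest.approx(beta * r / r2, abs=1e-8)

    def test_strong_sex_effect_dominates_between_level(self):
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(
                n_participants=250,
                beta_within={}, beta_between={"sex_W": -0.5, "bmi": 0.002},
                meal_attendance=1.0, snack_rate=0.0, missing_meal_rate=0.0,
                include_tee=False, zero_rate=0.0, seed=500 + seed,
            )
            participants, table = _simulate_prepared(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fit_meal_models(
                    table, participants, "energy", ("weekend",),
                    ("sex", "bmi", "age"), meals=("lunch",),
                )
            between = [r for r in res if r.level == "between"][0]
            if between.pratt is not None and between.pratt.idxmax() == "sex_W":
                hits += 1
        assert hits >= 8  # majority over seeds

    def test_between_correlation_structure_recovered(self):
        """Sigma_B recovers the generated participant-level association."""
        beta_sex = -0.4
        cfg = SimulationConfig(
            n_participants=600, var_participant=0.05, var_mealcell=0.0,
            var_occasion=0.2, beta_within={}, beta_between={"sex_W": beta_sex},
            meal_attendance=1.0, snack_rate=0.0, missing_meal_rate=0.0,
            include_tee=False, zero_rate=0.0, seed=77,
        )
        participants, table = _simulate_prepared(cfg)
        sub = table[table["meal_type"] == "breakfast"].merge(
            participants, on="participant_id"
        )
        z = pd.DataFrame(
            {"y": sub["log_energy"], "sex_W": (sub["sex"] == "W").astype(float)}
        )
        dec = decompose_two_level(z, sub["participant_id"].to_numpy())
        # true between covariance: cov(y*, sex) = beta * p(1-p)
        p_w = (participants["sex"] == "W").mean()
        expected_cov = beta_sex * p_w * (1 - p_w)
        assert dec.sigma_b.loc["y", "sex_W"] == pytest.approx(expected_cov, abs=0.02)
        expected_var = beta_sex**2 * p_w * (1 - p_w) + 0.05
        assert dec.sigma_b.loc["y", "y"] == pytest.approx(expected_var, abs=0.02)

    def test_scale_invariance_of_fitted_results(self, small_cohort):
        _, participants, intake = small_cohort
        table = compute_prior_interval(intake, occasion_order=None)
        table = select_meals(table)
        table, _ = exclude_zeros_log(table, "energy")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = fit_meal_models(
                table, participants, "energy", ("weekend", "place"), ("sex", "age"),
                meals=("dinner",),
            )
            scaled_table = table.copy()
            scaled_table["log_energy"] = table["log_energy"] * 4.0  # y -> y*4
            scaled = fit_meal_models(
                scaled_table, participants, "energy", ("weekend", "place"),
                ("sex", "age"), meals=("dinner",),
            )
        for b, s in zip(base, scaled):
            assert np.allclose(b.beta.to_numpy(), s.beta.to_numpy(), atol=1e-10)
            assert np.allclose(b.r.to_numpy(), s.r.to_numpy(), atol=1e-10)
            assert b.r2 == pytest.approx(s.r2, abs=1e-10)

    def test_requires_log_column(self, small_cohort):
        _, participants, intake = small_cohort
        with pytest.raises(ValidationError, match="exclude_zeros_log"):
            fit_meal_models(intake, participants, "energy", ("weekend",), ("sex",))

    def test_constant_covariate_dropped_with_warning(self, small_cohort):
        _, participants, intake = small_cohort
        table = select_meals(compute_prior_interval(intake, occasion_order=None))
        table, _ = exclude_zeros_log(table, "energy")
        table = table.copy()
        table["season"] = "winter"  # constant in every stratum
        with pytest.warns(UserWarning, match="constant covariate"):
            results = fit_meal_models(
                table, participants, "energy", ("weekend", "season"), ("sex",),
                meals=("lunch",),
            )
        within = [r for r in results if r.level == "within"][0]
        assert "season_summer" not in within.predictors
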