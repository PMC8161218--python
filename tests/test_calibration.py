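"""Design matrix, rank-deficient least squares, parameter assembly, comparisons."""

import numpy as np
import pandas as pd
import pytest

from etis.calibration import (
    DESIGN_COLUMNS,
    assemble_etis_from_fit,
    build_design_matrix,
    compare_indices,
    fit_least_squares,
    pearson_r,
    split_train_test,
)
from etis.model import FITTED_PARAMETERS, etis_values
from etis.synthetic import GeneratorConfig, generate_environment


class TestDesignMatrix:
    def test_column_order_and_frozen_row(self):
        x = build_design_matrix([28.7], [65.8], [0.07])
        assert list(x.columns) == DESIGN_COLUMNS
        row = x.iloc[0]
        assert row["intercept"] == 1.0
        assert row["T"] == row["T_dup"] == 28.7
        assert row["50T"] == pytest.approx(50 * 28.7)
        assert row["RH_T"] == pytest.approx(65.8 * 28.7)
        # u^0.6827 * (38 - T) = 0.1627 * 9.3
        assert row["u_pow_Ts_minus_T"] == pytest.approx(1.513, abs=1e-3)
        assert row["const_Ts"] == 38.0
        assert row["const_Ts_K4"] == pytest.approx(311.15**4)
        assert row["T_K4"] == pytest.approx(301.85**4)

    def test_velocity_column_vanishes_at_skin_temperature(self):
        x = build_design_matrix([38.0], [60.0], [0.25])
        assert x["u_pow_Ts_minus_T"].iloc[0] == 0.0

    def test_duplicate_temperature_columns(self, barn_env):
        x = build_design_matrix(barn_env)
        assert np.array_equal(x["T"], x["T_dup"])
        assert np.allclose(x["50T"], 50.0 * x["T"])

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            build_design_matrix([], [], [])


class TestSplit:
    def test_campaign_sizes(self):
        df = pd.DataFrame({"x": np.arange(1029)})
        train, test = split_train_test(df, fraction=0.7, seed=0)
        assert (len(train), len(test)) == (720, 309)

    def test_even_split(self):
        train, test = split_train_test(np.arange(10), fraction=0.5, seed=3)
        assert len(train) == len(test) == 5

    def test_deterministic_disjoint_exhaustive(self):
        df = pd.DataFrame({"x": np.arange(101)})
        a_train, a_test = split_train_test(df, seed=7)
        b_train, b_test = split_train_test(df, seed=7)
        pd.testing.assert_frame_equal(a_train, b_train)
        merged = sorted(a_train["x"].tolist() + a_test["x"].tolist())
        assert merged == list(range(101))
        assert set(a_train["x"]).isdisjoint(a_test["x"])

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(np.arange(5), fraction=0.7, seed=0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(np.arange(50), fraction=1.2, seed=0)


class TestLeastSquares:
    def test_noiseless_recovery_of_fitted_values(self, barn_env):
        x = build_design_matrix(barn_env)
        beta = np.array([1.0, 0.5, 0.0, 0.001, -0.3, 0.0, 0.0, 0.0, -4e-8])
        y = x.to_numpy() @ beta
        fit = fit_least_squares(x, y)
        assert np.max(np.abs(fit.predict(x) - y)) < 1e-8
        assert fit.r_squared(x, y) == pytest.approx(1.0, abs=1e-12)

    def test_design_is_rank_deficient(self, barn_env):
        x = build_design_matrix(barn_env)
        fit = fit_least_squares(x, np.asarray(etis_values(
            barn_env["air_temperature_C"], barn_env["relative_humidity_pct"],
            barn_env["air_velocity_ms"])))
        assert fit.rank < 9

    def test_null_space_invariance_of_predictions(self, barn_env):
        # shifting coefficient weight between the duplicate T columns
        # cannot change fitted values
        x = build_design_matrix(barn_env)
        y = np.asarray(etis_values(
            barn_env["air_temperature_C"], barn_env["relative_humidity_pct"],
            barn_env["air_velocity_ms"]))
        fit = fit_least_squares(x, y)
        shifted = fit.coefficients.copy()
        shifted["T"] += 0.123
        shifted["T_dup"] -= 0.123
        pred_shifted = x.to_numpy() @ shifted.to_numpy()
        assert np.max(np.abs(pred_shifted - fit.predict(x))) < 1e-9

    def test_noisy_rmse_tracks_noise_scale(self, rng):
        # skin temps simulated from the index structure + N(0, 0.5)
        env = generate_environment(GeneratorConfig(n=1000, seed=21))
        x = build_design_matrix(env)
        signal = np.asarray(etis_values(
            env["air_temperature_C"], env["relative_humidity_pct"],
            env["air_velocity_ms"]))
        rmses = []
        for rep in range(20):
            y = signal + rng.normal(0, 0.5, len(env))
            fit = fit_least_squares(x, y)
            rmses.append(np.sqrt(np.mean((fit.predict(x) - y) ** 2)))
        assert np.mean(rmses) == pytest.approx(0.5, rel=0.05)

    def test_constant_response_flagged(self, barn_env):
        x = build_design_matrix(barn_env)
        fit = fit_least_squares(x, np.full(len(barn_env), 34.0))
        with pytest.raises(ValueError):
            fit.r_squared(x, np.full(len(barn_env), 34.0))


class TestAssembleFromFit:
    def test_paper_convention_returns_canonical_constants(self, barn_env):
        x = build_design_matrix(barn_env)
        fit = fit_least_squares(x, np.asarray(etis_values(
            barn_env["air_temperature_C"], barn_env["relative_humidity_pct"],
            barn_env["air_velocity_ms"])))
        assert assemble_etis_from_fit(fit, "paper") == FITTED_PARAMETERS

    def test_direct_convention_recovers_generating_parameters(self, barn_env):
        x = build_design_matrix(barn_env)
        y = np.asarray(etis_values(
            barn_env["air_temperature_C"], barn_env["relative_humidity_pct"],
            barn_env["air_velocity_ms"]))
        params, mapping = assemble_etis_from_fit(fit_least_squares(x, y), "direct")
        assert params.humidity_coef == pytest.approx(0.0006, abs=1e-6)
        assert params.velocity_coef == pytest.approx(-0.3132, abs=1e-6)
        assert params.radiation_coef == pytest.approx(4.8957e-8, abs=1e-12)
        assert params.conduction_coef == pytest.approx(-4.79, abs=1e-6)
        assert params.conduction_reference_factor == pytest.approx(1.0086, abs=1e-6)
        assert "a" in mapping and "D" in mapping

    def test_direct_convention_preserves_predictions(self, barn_env):
        x = build_design_matrix(barn_env)
        y = np.asarray(etis_values(
            barn_env["air_temperature_C"], barn_env["relative_humidity_pct"],
            barn_env["air_velocity_ms"]))
        fit = fit_least_squares(x, y)
        params, _ = assemble_etis_from_fit(fit, "direct")
        assembled = etis_values(
            barn_env["air_temperature_C"], barn_env["relative_humidity_pct"],
            barn_env["air_velocity_ms"], params=params)
        assert pearson_r(assembled, fit.predict(x)) == pytest.approx(1.0, abs=1e-12)

    def test_unknown_convention_rejected(self, barn_env):
        x = build_design_matrix(barn_env)
        fit = fit_least_squares(x, np.asarray(barn_env["air_temperature_C"]))
        with pytest.raises(ValueError):
            assemble_etis_from_fit(fit, "stepwise")


class TestPearson:
    def test_perfect_linear(self):
        a = np.arange(10.0)
        assert pearson_r(a, 2 * a + 1) == pytest.approx(1.0)
        assert pearson_r(a, -a) == pytest.approx(-1.0)

    def test_independent_series_near_zero(self, rng):
        a, b = rng.normal(size=10_000), rng.normal(size=10_000)
        assert abs(pearson_r(a, b)) < 0.05

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(10), np.arange(10.0))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 2.0], [3.0, 4.0])


class TestCompareIndices:
    def test_sorted_descending_with_all_entries(self, barn_dataset):
        f = barn_dataset.frame
        report = compare_indices(f, f["skin_temperature_C"].to_numpy())
        assert len(report) == 12
        assert list(report["pearson_r"]) == sorted(report["pearson_r"], reverse=True)

    def test_index_structured_response_ranks_its_index_first(self, rng):
        env = generate_environment(GeneratorConfig(n=400, seed=31))
        signal = np.asarray(etis_values(
            env["air_temperature_C"], env["relative_humidity_pct"],
            env["air_velocity_ms"]))
        physio = signal + rng.normal(0, 0.3, len(env))
        report = compare_indices(env, physio)
        assert report["index"].iloc[0] == "etis"

    def test_misaligned_records_rejected(self, barn_env):
        with pytest.raises(ValueError):
            compare_indices(barn_env, np.ones(3))

    def test_single_entry_registry(self, barn_dataset):
        from etis.indices import REGISTRY

        f = barn_dataset.frame
        report = compare_indices(
            f, f["skin_temperature_C"].to_numpy(),
            registry={"etis": REGISTRY["etis"]},
        )
        assert len(report) == 1
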