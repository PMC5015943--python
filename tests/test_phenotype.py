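"""PC150 derivation: normalisation, fitting, inversion, fallback, transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import airwayqtl as aq
from airwayqtl.phenotype import PhenotypeUndefined, _pc_for_series

from conftest import smallest_admissible_root_by_grid


def series(doses, responses, mouse="m1", session="baseline1", truncated=False):
    return aq.DoseResponseSeries(mouse, session, np.array(doses, float),
                                 np.array(responses, float), truncated)


class TestPercentControl:
    @pytest.mark.parametrize(
        "doses,resp,expected",
        [
            ([0, 3.1], [0.5, 0.5], [100, 100]),
            ([0, 12.5], [0.4, 1.0], [100, 250]),
            ([0, 3.1, 6.2], [0.25, 0.5, 1.0], [100, 200, 400]),
        ],
    )
    def test_ratio_times_100(self, doses, resp, expected):
        out = aq.percent_control(series(doses, resp))
        np.testing.assert_allclose(out.responses, expected)
        assert out.responses[0] == 100.0

    def test_nonpositive_baseline_flags_phenotype(self):
        with pytest.raises(PhenotypeUndefined, match="dose-0"):
            aq.percent_control(series([0, 3.1], [0.0, 0.5]))
        with pytest.raises(PhenotypeUndefined, match="dose-0"):
            aq.percent_control(series([3.1, 6.2], [0.5, 0.6]))


class TestAverageBaselines:
    def test_single_replicate_passthrough(self):
        s = series([0, 3.1, 6.2], [0.5, 0.7, 1.0])
        assert aq.average_baselines(s, None) is s

    def test_idempotent_on_equal_series(self):
        s = series([0, 3.1, 6.2], [0.5, 0.7, 1.0])
        out = aq.average_baselines(s, series([0, 3.1, 6.2], [0.5, 0.7, 1.0],
                                             session="baseline2"))
        np.testing.assert_allclose(out.responses, s.responses)

    def test_dosewise_mean(self):
        out = aq.average_baselines(
            series([0, 3.1], [100, 200]),
            series([0, 3.1], [100, 300], session="baseline2"),
        )
        np.testing.assert_allclose(out.responses, [100, 250])

    def test_truncated_replicate_uses_available_values(self):
        out = aq.average_baselines(
            series([0, 3.1, 6.2, 12.5], [0.4, 0.6, 0.9, 1.5]),
            series([0, 3.1], [0.6, 0.8], session="baseline2", truncated=True),
        )
        np.testing.assert_allclose(out.responses, [0.5, 0.7, 0.9, 1.5])
        assert out.truncated

    def test_no_common_doses_flags(self):
        with pytest.raises(PhenotypeUndefined, match="fewer than 2"):
            aq.average_baselines(
                series([0, 3.1], [1, 2]),
                series([6.2, 12.5], [3, 4], session="baseline2"),
            )


class TestQuadraticFit:
    def test_exact_quadratic_recovered(self):
        d = np.array([0, 3.1, 6.2, 12.5, 25.0])
        fit = aq.fit_dose_response(series(d, 100 + 2 * d + d**2))
        assert (fit.alpha, fit.beta1, fit.beta2) == pytest.approx((100, 2, 1))
        assert fit.rss == pytest.approx(0, abs=1e-18)

    def test_three_points_interpolate(self):
        fit = aq.fit_dose_response(series([0, 5, 10], [100, 180, 400]))
        assert fit.rss == pytest.approx(0, abs=1e-16)
        assert fit.n_points == 3

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            d = np.sort(np.concatenate([[0], rng.uniform(1, 25, 4)]))
            y = 100 + rng.normal(0, 20, 5).cumsum()
            X = np.column_stack([np.ones(5), d, d**2])
            oracle = np.linalg.solve(X.T @ X, X.T @ y)
            fit = aq.fit_dose_response(series(d, y))
            np.testing.assert_allclose(
                [fit.alpha, fit.beta1, fit.beta2], oracle, atol=1e-8
            )

    def test_two_points_fall_back_to_line(self):
        fit = aq.fit_dose_response(series([0, 6.2], [100, 162]))
        assert fit.kind == "linear"
        assert fit.beta1 == pytest.approx(10.0)

    def test_single_point_undefined(self):
        with pytest.raises(PhenotypeUndefined):
            aq.fit_dose_response(series([0], [100]))


class TestInvertPC:
    def test_linear_case(self):
        fit = aq.QuadraticFit(100, 10, 0, 0, 5)
        assert aq.invert_pc(fit, 150, max_dose=25) == pytest.approx(5.0)

    def test_pure_quadratic_case(self):
        fit = aq.QuadraticFit(100, 0, 2, 0, 5)
        assert aq.invert_pc(fit, 150, max_dose=25) == pytest.approx(5.0)

    def test_two_positive_roots_take_smaller(self):
        fit = aq.QuadraticFit(100, -30, 5, 0, 5)
        got = aq.invert_pc(fit, 150, max_dose=25)
        oracle = smallest_admissible_root_by_grid(100, -30, 5, 150, 50.0)
        assert got == pytest.approx(oracle, abs=1e-9)

    def test_decreasing_curve_unresponsive(self):
        fit = aq.QuadraticFit(100, -1, 0, 0, 5)
        assert aq.invert_pc(fit, 150, max_dose=25) is None

    def test_root_beyond_extrapolation_cap_unresponsive(self):
        fit = aq.QuadraticFit(100, 0.5, 0, 0, 5)  # crosses 150 at d=100
        assert aq.invert_pc(fit, 150, max_dose=25, extrapolation_cap=2.0) is None

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        beta2=st.floats(0.01, 1.0),
        pc=st.floats(0.5, 40.0),
    )
    def test_inversion_is_exact_inverse_of_construction(self, beta2, pc):
        beta1 = 50.0 / pc - beta2 * pc
        fit = aq.QuadraticFit(100.0, beta1, beta2, 0, 5)
        root = aq.invert_pc(fit, 150.0, max_dose=25.0, extrapolation_cap=10.0)
        assert root == pytest.approx(pc, abs=1e-8)
        assert fit.predict(root) == pytest.approx(150.0, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        beta1=st.floats(-20, 20),
        beta2=st.floats(0.01, 2.0),
    )
    def test_threshold_monotonicity(self, beta1, beta2):
        fit = aq.QuadraticFit(100.0, beta1, beta2, 0, 5)
        pc150 = aq.invert_pc(fit, 150, max_dose=25, extrapolation_cap=10.0)
        pc200 = aq.invert_pc(fit, 200, max_dose=25, extrapolation_cap=10.0)
        if pc150 is not None and pc200 is not None:
            assert pc200 >= pc150 - 1e-12


class TestLinearFallback:
    def test_rootless_quadratic_with_upward_trend_uses_line(self):
        # concave-down quadratic never reaching 150, but points trend upward
        d = np.array([0, 3.1, 6.2, 12.5, 25.0])
        y = np.array([100, 112, 121, 130, 135.0])
        s = series(d, y)
        value, kind, fallback = _pc_for_series(s, 150, 25.0, 2.0)
        quad = aq.fit_dose_response(s)
        assert aq.invert_pc(quad, 150, 25.0, 2.0) is None
        assert fallback and kind == "linear" and value is not None

    def test_fallback_not_invoked_when_quadratic_admissible(self):
        d = np.array([0, 3.1, 6.2, 12.5, 25.0])
        s = series(d, 100 + 2 * d + 0.5 * d**2)
        value, kind, fallback = _pc_for_series(s, 150, 25.0, 2.0)
        assert kind == "quadratic" and not fallback

    def test_both_rootless_is_undefined(self):
        d = np.array([0, 3.1, 6.2, 12.5, 25.0])
        s = series(d, [100, 99, 98, 97, 96])
        value, kind, fallback = _pc_for_series(s, 150, 25.0, 2.0)
        assert value is None and not fallback


class TestBuildPhenotypes:
    def _penh_table(self, curves):
        rows = []
        for mouse, session, b1, b2, scale in curves:
            for d in (0.0, 3.1, 6.2, 12.5, 25.0):
                pc = 100 + b1 * d + b2 * d * d
                rows.append((mouse, session, d, scale * pc / 100.0, 0))
        return pd.DataFrame(
            rows, columns=["mouse_id", "session", "dose_mg_ml", "penh", "truncated"]
        )

    def test_delta_is_baseline_minus_final(self):
        # baseline curve crosses 150 at 5.0; final at 2.0
        penh = self._penh_table(
            [("m1", "baseline1", 10.0, 0.0, 0.5),
             ("m1", "baseline2", 10.0, 0.0, 0.5),
             ("m1", "final", 25.0, 0.0, 0.5)]
        )
        out = aq.build_phenotypes(penh)
        assert out.loc[0, "pc150_baseline"] == pytest.approx(5.0)
        assert out.loc[0, "pc150_final"] == pytest.approx(2.0)
        assert out.loc[0, "delta"] == pytest.approx(3.0)
        assert out.loc[0, "ln_baseline"] == pytest.approx(np.log(5.0))

    def test_negative_delta_retained(self):
        penh = self._penh_table(
            [("m1", "baseline1", 25.0, 0.0, 0.5),
             ("m1", "final", 10.0, 0.0, 0.5)]
        )
        out = aq.build_phenotypes(penh)
        assert out.loc[0, "delta"] == pytest.approx(-3.0)
        assert out.loc[0, "status"] == "ok"

    def test_identical_sessions_give_zero_delta(self):
        penh = self._penh_table(
            [("m1", "baseline1", 10.0, 0.2, 0.5),
             ("m1", "final", 10.0, 0.2, 0.5)]
        )
        out = aq.build_phenotypes(penh)
        assert out.loc[0, "delta"] == pytest.approx(0.0, abs=1e-12)

    def test_unresponsive_mouse_flagged_not_crashed(self):
        penh = self._penh_table(
            [("flat", "baseline1", 0.1, 0.0, 0.5),
             ("flat", "final", 10.0, 0.0, 0.5)]
        )
        out = aq.build_phenotypes(penh)
        assert out.loc[0, "status"] == "undefined_baseline"
        assert out.loc[0, "undefined_reason_baseline"] == "unresponsive"
        assert np.isnan(out.loc[0, "pc150_baseline"])
        assert not np.isnan(out.loc[0, "pc150_final"])

    def test_duplicate_doses_averaged(self):
        penh = self._penh_table(
            [("m1", "baseline1", 10.0, 0.0, 0.5), ("m1", "final", 10.0, 0.0, 0.5)]
        )
        dup = penh[penh["session"] == "baseline1"].copy()
        penh2 = pd.concat([penh, dup], ignore_index=True)
        out = aq.build_phenotypes(penh2)
        assert out.loc[0, "pc150_baseline"] == pytest.approx(5.0)

    def test_printed_strain_mean_arithmetic(self):
        # delta definition applied to published-style per-strain means
        assert aq.delta_pc150(5.05, 1.96) == pytest.approx(3.09)
        assert aq.delta_pc150(5.98, 7.04) == pytest.approx(-1.06)
        assert round(float(aq.relative_change_percent(5.05, 1.96))) == 61


class TestTransformDiagnostics:
    def test_lognormal_sample_suggests_ln(self):
        rng = np.random.default_rng(0)
        prof = aq.boxcox_profile(rng.lognormal(1.0, 0.8, 200))
        assert prof["suggested"] == "ln"
        assert prof["ci"][0] <= 0.0 <= prof["ci"][1]

    def test_shifted_normal_sample_covers_one(self):
        rng = np.random.default_rng(1)
        prof = aq.boxcox_profile(rng.normal(50.0, 2.0, 200))
        assert prof["ci"][0] <= 1.0 <= prof["ci"][1]

    def test_constant_vector_degenerate(self):
        prof = aq.boxcox_profile(np.full(20, 3.0))
        assert prof["degenerate"]

    def test_nonpositive_values_error_lists_mice(self):
        with pytest.raises(ValueError, match="m2"):
            aq.boxcox_profile(np.array([1.0, -1.0]), mouse_ids=["m1", "m2"])


class TestResistanceCollapse:
    def test_cycle_means(self):
        cycles = pd.DataFrame(
            {"dose_mg_ml": [0.0] * 3 + [6.25] * 3, "time": range(6),
             "resistance": [1.2, 1.2, 1.2, 1.0, 2.0, 3.0]}
        )
        s = aq.collapse_resistance(cycles, "r1")
        np.testing.assert_allclose(s.responses, [1.2, 2.0])

    def test_two_path_equivalence(self):
        # PC150 from raw cycles equals PC150 from the per-dose means
        rng = np.random.default_rng(2)
        doses = [0.0, 6.25, 12.5, 25.0]
        means = [1.0, 1.3, 1.8, 2.6]
        rows = []
        for d, m in zip(doses, means):
            vals = m + rng.normal(0, 0.05, 90)
            vals[-1] = m * 90 - vals[:-1].sum()  # force the exact mean
            for t, v in enumerate(vals):
                rows.append((d, t, v))
        cycles = pd.DataFrame(rows, columns=["dose_mg_ml", "time", "resistance"])
        s = aq.collapse_resistance(cycles, "r1")
        direct = aq.DoseResponseSeries("r1", "resistance", np.array(doses),
                                       np.array(means))
        pc_a, _, _ = _pc_for_series(s, 150, 25.0, 2.0)
        pc_b, _, _ = _pc_for_series(direct, 150, 25.0, 2.0)
        assert pc_a == pytest.approx(pc_b, abs=1e-9)

    def test_missing_zero_dose_flagged(self):
        cycles = pd.DataFrame({"dose_mg_ml": [6.25] * 3, "resistance": [1, 2, 3]})
        with pytest.raises(PhenotypeUndefined, match="dose-0"):
            aq.collapse_resistance(cycles)


class TestPhenotyperEstimator:
    def test_sklearn_params_roundtrip(self):
        est = aq.PC150Phenotyper(threshold=200.0)
        assert est.get_params()["threshold"] == 200.0
        est.set_params(extrapolation_cap=3.0)
        assert est.extrapolation_cap == 3.0

    def test_transform_sets_exclusion_attributes(self):
        t = TestBuildPhenotypes()
        penh = t._penh_table(
            [("m1", "baseline1", 10.0, 0.0, 0.5), ("m1", "final", 10.0, 0.0, 0.5),
             ("flat", "baseline1", 0.1, 0.0, 0.5), ("flat", "final", 0.1, 0.0, 0.5)]
        )
        est = aq.PC150Phenotyper()
        with pytest.warns(UserWarning, match="undefined PC150"):
            out = est.fit_transform(penh)
        assert est.n_mice_ == 2 and est.n_excluded_ == 1
        assert set(out["status"]) == {"ok", "undefined_both"}
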