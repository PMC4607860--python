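import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from satkit import (
    ConfigError,
    EstimationError,
    ExponentialSAT,
    SATParams,
    adjusted_r2,
    evaluate_sat,
    objective_sse,
    parse_model_spec,
)

finite = st.floats(allow_nan=False, allow_infinity=False)


class TestEvaluateSat:
    def test_zero_before_intercept(self):
        p = SATParams(lam=2.0, beta=1.0, delta=1.0)
        assert evaluate_sat(p, 0.5) == 0.0
        assert evaluate_sat(p, 1.0) == 0.0

    def test_closed_form_value(self):
        # 2 * (1 - e^-1), independent arithmetic
        p = SATParams(lam=2.0, beta=1.0, delta=1.0)
        assert evaluate_sat(p, 2.0) == pytest.approx(2.0 * (1 - np.exp(-1)), rel=1e-12)
        assert evaluate_sat(p, 2.0) == pytest.approx(1.26424, abs=1e-5)

    def test_asymptote_limit(self):
        p = SATParams(lam=2.0, beta=1.0, delta=1.0)
        assert evaluate_sat(p, 1e6) == pytest.approx(2.0)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        lam=st.floats(0.0, 6.0),
        beta=st.floats(0.05, 6.0),
        delta=st.floats(0.0, 3.0),
        t1=st.floats(-1.0, 10.0),
        dt=st.floats(0.0, 5.0),
    )
    def test_nondecreasing_in_time_and_asymptote(self, lam, beta, delta, t1, dt):
        p = SATParams(lam=lam, beta=beta, delta=delta)
        assert evaluate_sat(p, t1 + dt) >= evaluate_sat(p, t1) - 1e-12
        p_hi = SATParams(lam=lam + 1.0, beta=beta, delta=delta)
        if t1 > delta:
            assert evaluate_sat(p_hi, t1) >= evaluate_sat(p, t1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(beta=st.floats(0.05, 3.0), factor=st.floats(1.01, 4.0))
    def test_rate_steepens_without_changing_asymptote(self, beta, factor):
        lam, delta, t = 2.0, 0.5, 1.5
        low = evaluate_sat(SATParams(lam, beta, delta), t)
        high = evaluate_sat(SATParams(lam, beta * factor, delta), t)
        assert high >= low
        # asymptote unchanged
        assert evaluate_sat(SATParams(lam, beta * factor, delta), 1e7) == pytest.approx(
            lam, rel=1e-5
        )

    def test_parameter_validation(self):
        with pytest.raises(ConfigError):
            SATParams(lam=-0.1, beta=1.0, delta=0.0)
        with pytest.raises(ConfigError):
            SATParams(lam=1.0, beta=0.0, delta=0.0)
        with pytest.raises(ConfigError):
            SATParams(lam=1.0, beta=1.0, delta=-1.0)


class TestParseModelSpec:
    def test_null_model(self):
        spec = parse_model_spec("1λ-1β-1δ")
        assert spec.k == 3
        assert spec.lambda_map == spec.beta_map == spec.delta_map == (1, 1, 1)

    def test_preferred_model_grouping(self):
        spec = parse_model_spec("3λ-1β-2δ")
        assert spec.k == 6
        assert spec.lambda_map == (1, 2, 3)
        assert spec.delta_map == (1, 2, 2)  # NoInterp vs interpolated preset

    def test_saturated(self):
        spec = parse_model_spec("3λ-3β-3δ")
        assert spec.k == 9

    def test_ascii_spellings(self):
        assert parse_model_spec("3L-2B-1D").name == "3λ-2β-1δ"
        assert parse_model_spec("3lambda-1beta-2delta").name == "3λ-1β-2δ"

    def test_count_exceeding_conditions_rejected(self):
        with pytest.raises(ConfigError):
            parse_model_spec("4λ-1β-1δ")

    def test_bad_name_rejected(self):
        with pytest.raises(ConfigError):
            parse_model_spec("3λ-1β")

    def test_explicit_grouping_override(self):
        spec = parse_model_spec("1λ-1β-2δ", delta_map=(1, 1, 2))
        assert spec.delta_map == (1, 1, 2)

    def test_unpack_pack_round_trip(self):
        spec = parse_model_spec("3λ-1β-2δ")
        theta = np.array([3.0, 2.0, 1.0, 0.8, 0.5, 1.2])
        assert np.allclose(spec.pack(spec.unpack(theta)), theta)


class TestObjectiveSSE:
    def _curves(self, spec, theta, times):
        per = spec.unpack(theta)
        rows = [
            {"condition": c, "lag_time": t, "dprime": evaluate_sat(p, t)}
            for c, p in per.items()
            for t in times
        ]
        return pd.DataFrame(rows)

    def test_zero_at_generating_theta(self, post_onset_times):
        spec = parse_model_spec("3λ-1β-2δ")
        theta = np.array([3.0, 2.0, 1.0, 0.8, 0.5, 1.2])
        curves = self._curves(spec, theta, post_onset_times)
        assert objective_sse(theta, spec, curves) == pytest.approx(0.0, abs=1e-20)

    def test_single_point_unit_error(self):
        spec = parse_model_spec("1λ-1β-1δ", conditions=("NoInterp",))
        curves = pd.DataFrame(
            [{"condition": "NoInterp", "lag_time": 0.5, "dprime": 1.0}]
        )
        theta = np.array([0.0, 1.0, 3.0])  # model value 0 everywhere
        assert objective_sse(theta, spec, curves) == pytest.approx(1.0)

    def test_matches_brute_force_loop(self, post_onset_times):
        rng = np.random.default_rng(4)
        spec = parse_model_spec("3λ-2β-1δ")
        theta = np.array([3.1, 2.2, 1.3, 1.4, 0.6, 0.7])
        curves = self._curves(spec, theta, post_onset_times)
        curves["dprime"] += rng.normal(0, 0.3, len(curves))
        probe = np.array([2.5, 2.0, 1.0, 1.0, 1.0, 0.9])
        # independent per-point loop oracle
        per = spec.unpack(probe)
        total = 0.0
        for row in curves.itertuples(index=False):
            p = per[row.condition]
            pred = (
                p.lam * (1 - np.exp(-p.beta * (row.lag_time - p.delta)))
                if row.lag_time > p.delta
                else 0.0
            )
            total += (row.dprime - pred) ** 2
        assert objective_sse(probe, spec, curves) == pytest.approx(total, rel=1e-12)


class TestAdjustedR2:
    def test_perfect_prediction(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert adjusted_r2(obs, obs, k=2) == pytest.approx(1.0)

    def test_hand_computed_zero(self):
        # SS_res = 2, SS_tot = 2, n=2, k=1 -> 1 - (2/1)/(2/1) = 0
        assert adjusted_r2([0.0, 2.0], [1.0, 1.0], k=1) == pytest.approx(0.0)

    def test_mean_prediction_is_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.full(3, obs.mean())
        assert adjusted_r2(obs, pred, k=1) == pytest.approx(0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.1, 50.0),
        shift=st.floats(-100.0, 100.0),
    )
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(1)
        obs = rng.normal(size=12)
        pred = obs + rng.normal(0, 0.5, size=12)
        a = adjusted_r2(obs, pred, k=3)
        b = adjusted_r2(scale * obs + shift, scale * pred + shift, k=3)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-9)

    def test_df_and_variance_errors(self):
        with pytest.raises(EstimationError, match="n > k"):
            adjusted_r2([1.0, 2.0], [1.0, 2.0], k=2)
        with pytest.raises(EstimationError, match="zero variance"):
            adjusted_r2([1.0, 1.0, 1.0], [1.0, 1.0, 0.0], k=1)


class TestExponentialSATModel:
    def test_results_carry_summary(self, post_onset_times):
        spec = parse_model_spec("3λ-1β-2δ")
        theta = np.array([3.0, 2.0, 1.0, 0.8, 0.5, 1.2])
        per = spec.unpack(theta)
        rows = [
            {"condition": c, "lag_time": t, "dprime": evaluate_sat(p, t)}
            for c, p in per.items()
            for t in post_onset_times
        ]
        model = ExponentialSAT(pd.DataFrame(rows), spec)
        res = model.results(theta)
        assert res.rsquared_adj == pytest.approx(1.0)
        text = res.summary()
        assert "3λ-1β-2δ" in text and "lambda1" in text
        assert res.params["beta1"] == pytest.approx(0.8)
        by_cond = res.params_by_condition
        assert by_cond.loc["OR", "delta"] == pytest.approx(1.2)

    def test_missing_condition_rejected(self):
        spec = parse_model_spec("3λ-1β-2δ")
        df = pd.DataFrame([{"condition": "NoInterp", "lag_time": 1.0, "dprime": 1.0}])
        with pytest.raises(Exception, match="OR"):
            ExponentialSAT(df, spec)
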