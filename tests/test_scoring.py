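import numpy as np
import pandas as pd
import pytest
from scipy import stats

from satkit import (
    CohortSpec,
    DataError,
    DesignSpec,
    cr_profile,
    dprime_curves,
    empirical_asymptote,
    evaluate_sat,
    lag_times,
    simulate_cohort,
)


def make_trials(codes_by_type, n_per=4, participant="P1", spec=None):
    """Build a lag-code trial table where every trial of a type shares codes."""
    spec = spec or DesignSpec()
    lag_cols = [f"lag_{k}" for k in range(1, spec.n_tones + 1)]
    rows = []
    trial = 0
    for stype, codes in codes_by_type.items():
        cons, acc, ctrl = spec.type_map[stype]
        for _ in range(n_per):
            row = {
                "participant": participant,
                "list": 0,
                "trial": trial,
                "item": trial,
                "sentence_type": stype,
                "construction": cons,
                "acceptable": acc,
                "control_anomaly": ctrl,
            }
            row.update(dict(zip(lag_cols, codes)))
            rows.append(row)
            trial += 1
    return pd.DataFrame(rows)


ALL_TYPES_BOTH = {t: ["BOTH"] * 15 for t in DesignSpec().type_map}


class TestDPrimeCurves:
    def test_all_both_gives_zero_dprime(self, design):
        trials = make_trials(ALL_TYPES_BOTH)
        curves = dprime_curves(trials, design)
        assert np.allclose(curves["dprime"], 0.0)

    def test_hand_computed_dprime(self, design):
        # hit = 0.75, fa = 0.25 with N=4 -> d' = 2 * Phi^-1(0.75)
        codes = {t: ["BOTH"] * 15 for t in design.type_map}
        codes["T1"] = ["YES"] * 15
        codes["T2"] = ["YES"] * 15
        trials_var = []
        # 3 of 4 T1 trials YES, 1 NO; 1 of 4 T2 trials YES, 3 NO
        base = make_trials(codes)
        lag_cols = [f"lag_{k}" for k in range(1, 16)]
        t1_idx = base.index[base.sentence_type == "T1"]
        t2_idx = base.index[base.sentence_type == "T2"]
        base.loc[t1_idx[3], lag_cols] = "NO"
        base.loc[t2_idx[1:], lag_cols] = "NO"
        curves = dprime_curves(base, design)
        got = curves[(curves.participant == "P1") & (curves.condition == "NoInterp")]
        expected = 2 * stats.norm.ppf(0.75)
        assert np.allclose(got["dprime"], expected)

    def test_quantile_oracle_value(self):
        # d'(0.84, 0.16) computed through two independent inverse-normal calls
        assert stats.norm.ppf(0.84) - stats.norm.ppf(0.16) == pytest.approx(
            1.9889, abs=1e-4
        )

    def test_edge_correction_bounds_dprime(self, design):
        codes = {t: ["BOTH"] * 15 for t in design.type_map}
        codes["T1"] = ["YES"] * 15  # perfect hits
        codes["T2"] = ["NO"] * 15  # zero false alarms
        trials = make_trials(codes, n_per=8)
        curves = dprime_curves(trials, design)
        got = curves[(curves.participant == "P1") & (curves.condition == "NoInterp")]
        bound = 2 * stats.norm.ppf(1 - 1 / (2 * 8))
        assert np.allclose(got["dprime"], bound)
        assert np.isfinite(curves["dprime"]).all()

    def test_antisymmetric_under_label_swap(self, design):
        rng = np.random.default_rng(0)
        codes = {
            t: rng.choice(["YES", "NO", "BOTH"], size=15).tolist()
            for t in design.type_map
        }
        trials = make_trials(codes, n_per=6)
        swapped = trials.copy()
        swapped["acceptable"] = ~swapped["acceptable"]
        a = dprime_curves(trials, design).set_index(["participant", "condition", "lag"])
        b = dprime_curves(swapped, design).set_index(
            ["participant", "condition", "lag"]
        )
        assert np.allclose(a["dprime"], -b["dprime"])

    def test_average_pools_counts_before_z(self, design):
        # two participants with different hit rates: pooled z != mean of zs
        t_a = make_trials(
            {**ALL_TYPES_BOTH, "T1": ["YES"] * 15, "T2": ["NO"] * 15},
            n_per=4,
            participant="P1",
        )
        t_b = make_trials(
            {**ALL_TYPES_BOTH, "T1": ["BOTH"] * 15, "T2": ["NO"] * 15},
            n_per=4,
            participant="P2",
        )
        trials = pd.concat([t_a, t_b], ignore_index=True)
        pooled = dprime_curves(trials, design, average_method="pool")
        meaned = dprime_curves(trials, design, average_method="mean")
        avg_pool = pooled[
            (pooled.participant == "average") & (pooled.condition == "NoInterp")
        ]["dprime"].iloc[0]
        avg_mean = meaned[
            (meaned.participant == "average") & (meaned.condition == "NoInterp")
        ]["dprime"].iloc[0]
        # pooled: hit = (4*1 + 4*0.5)/8 = 0.75 ; fa = 1/16
        hit, fa = 0.75, 1 / 16
        expected_pool = stats.norm.ppf(hit) - stats.norm.ppf(fa)
        assert avg_pool == pytest.approx(expected_pool)
        assert avg_mean != pytest.approx(avg_pool)

    def test_empty_cell_raises_named_error(self, design):
        trials = make_trials(ALL_TYPES_BOTH)
        trials = trials[trials.sentence_type != "T2"]  # no NoInterp unacceptable
        with pytest.raises(DataError, match="unacceptable"):
            dprime_curves(trials, design)

    def test_converges_to_generating_curve(self, design):
        # with many trials and no heterogeneity the averaged curve approaches
        # the generating SAT function at every post-onset lag
        cs = CohortSpec(
            n_participants=4,
            trials_per_cell=192,
            lambda_sd=0.0,
            beta_log_sd=0.0,
            delta_sd=0.0,
            ability_slope_lambda=0.0,
        )
        sim = simulate_cohort(cs, seed=17)
        curves = dprime_curves(sim["trials"], design)
        avg = curves[curves.participant == "average"]
        worst = 0.0
        for cond, p in cs.true_params.items():
            sub = avg[avg.condition == cond].sort_values("lag")
            model = evaluate_sat(p, sub["lag_time"].to_numpy())
            worst = max(worst, np.abs(sub["dprime"].to_numpy() - model).max())
        assert worst < 0.25


class TestEmpiricalAsymptote:
    def test_mean_of_last_four(self):
        assert empirical_asymptote([0.0, 1.0, 2.0, 3.0, 4.0], m=4) == pytest.approx(2.5)

    def test_constant_curve(self):
        assert empirical_asymptote([2.0] * 10) == pytest.approx(2.0)

    def test_m_one_is_last_value(self):
        assert empirical_asymptote([1.0, 2.0, 9.0], m=1) == pytest.approx(9.0)

    def test_m_too_large_raises(self):
        with pytest.raises(ValueError):
            empirical_asymptote([1.0, 2.0], m=3)


class TestCRProfile:
    def test_all_both_is_half(self, design):
        trials = make_trials(ALL_TYPES_BOTH)
        prof = cr_profile(trials, design)
        assert np.allclose(prof["cr_rate"], 0.5)
        assert set(prof["group"]) == {"control", "experimental"}

    def test_all_no_last_lag_is_one(self, design):
        codes = {t: ["BOTH"] * 14 + ["NO"] for t in design.type_map}
        prof = cr_profile(make_trials(codes), design)
        last = prof[prof.lag == 15]
        assert np.allclose(last["cr_rate"], 1.0)

    def test_simulated_profiles_grow_from_half(self, design):
        sim = simulate_cohort(CohortSpec(n_participants=8, trials_per_cell=24), seed=3)
        prof = cr_profile(sim["trials"], design)
        for grp in ("control", "experimental"):
            sub = prof[prof.group == grp].sort_values("lag")
            rates = sub["cr_rate"].to_numpy()
            assert rates[0] == pytest.approx(0.5, abs=0.05)
            assert rates[-1] > 0.55
            # monotone trend: late mean well above early mean
            assert rates[-4:].mean() > rates[:4].mean() + 0.1
        # experimental (sentence-final anomaly) ends above the control group
        ctrl = prof[prof.group == "control"].sort_values("lag")["cr_rate"].to_numpy()
        expe = prof[prof.group == "experimental"].sort_values("lag")["cr_rate"].to_numpy()
        assert expe[-4:].mean() > ctrl[-4:].mean()
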