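import numpy as np
import pandas as pd
import pytest

from satkit import EstimationError, mixed_anova, pairwise_contrasts

CONDS = ("NoInterp", "OR", "OR+SR")


def make_table(values, quantity="lambda", abilities=None):
    """values: dict participant -> dict condition -> value"""
    rows = []
    for p, per in values.items():
        for c, v in per.items():
            row = {"participant": p, "condition": c, "quantity": quantity, "value": v}
            if abilities is not None:
                row["ability"] = abilities[p]
            rows.append(row)
    return pd.DataFrame(rows)


def random_table(rng, n=12, cond_means=(2.7, 1.5, 0.8), part_sd=0.3, noise=0.2,
                 slope=0.0, abilities=None):
    values, abil = {}, {}
    for i in range(n):
        p = f"P{i:02d}"
        z = rng.normal()
        shift = rng.normal(0, part_sd)
        abil[p] = 96.41 + 13.6 * z
        values[p] = {
            c: m + shift + slope * z + rng.normal(0, noise)
            for c, m in zip(CONDS, cond_means)
        }
    return make_table(values, abilities=abil)


class TestMixedAnova:
    def test_no_effect_when_means_identical(self):
        rng = np.random.default_rng(0)
        table = random_table(rng, cond_means=(2.0, 2.0, 2.0), noise=0.3)
        res = mixed_anova(table, "lambda")
        row = res.effects[res.effects.effect == "Construction"].iloc[0]
        assert row.p > 0.05

    def test_satterthwaite_df_match_balanced_design(self):
        rng = np.random.default_rng(1)
        table = random_table(rng, n=5)
        res = mixed_anova(table, "lambda")
        row = res.effects[res.effects.effect == "Construction"].iloc[0]
        assert (row.df_num, row.df_den) == (2, 8)
        table22 = random_table(rng, n=22, slope=0.3)
        res22 = mixed_anova(table22, "lambda", fixed=("construction", "ability", "interaction"))
        eff = res22.effects.set_index("effect")
        assert eff.loc["Construction", "df_den"] == 40
        assert eff.loc["Ability", "df_den"] == 20
        assert eff.loc["Construction x Ability", "df_den"] == 40

    def test_strong_condition_effect_detected_and_ordered(self):
        rng = np.random.default_rng(2)
        table = random_table(rng, n=8, noise=0.1, part_sd=0.2)
        res = mixed_anova(table, "lambda")
        row = res.effects[res.effects.effect == "Construction"].iloc[0]
        assert row.F > 10 and row.p < 0.001
        con = res.contrasts.set_index("pair")
        assert con.loc["NoInterp vs OR", "t"] > 0
        assert con.loc["NoInterp vs OR+SR", "t"] > con.loc["OR vs OR+SR", "t"] > 0

    def test_matches_direct_gls_oracle(self):
        # balanced random-intercept model: REML variance components from the
        # classical mean squares, then GLS fixed effects and a Wald F.
        rng = np.random.default_rng(3)
        table = random_table(rng, n=6, noise=0.25, part_sd=0.4)
        res = mixed_anova(table, "lambda")
        wide = table.pivot(index="participant", columns="condition", values="value")
        y = wide.to_numpy()
        n, J = y.shape
        grand = y.mean()
        ms_subj = J * ((y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        cell = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + grand
        ms_err = (cell**2).sum() / ((n - 1) * (J - 1))
        # classical balanced-design F for the within factor
        ms_cond = n * ((y.mean(axis=0) - grand) ** 2).sum() / (J - 1)
        f_classical = ms_cond / ms_err
        row = res.effects[res.effects.effect == "Construction"].iloc[0]
        assert row.F == pytest.approx(f_classical, rel=5e-3)
        assert row.df_den == (n - 1) * (J - 1)
        # and the mixed model's variance components agree with the ANOVA ones
        fit = res.mixed_result
        assert float(fit.scale) == pytest.approx(ms_err, rel=5e-2)
        assert float(fit.cov_re.iloc[0, 0]) == pytest.approx(
            max((ms_subj - ms_err) / J, 0.0), rel=5e-2, abs=1e-3
        )

    def test_single_participant_is_estimation_error(self):
        table = make_table({"P1": dict(zip(CONDS, (1.0, 2.0, 3.0)))})
        with pytest.raises(EstimationError):
            mixed_anova(table, "lambda")

    def test_ability_effect_on_lambda_only(self):
        # one simulated-style table: slope on lambda, none on delta
        rng = np.random.default_rng(4)
        lam = random_table(rng, n=22, slope=0.45, noise=0.2)
        abil = lam.groupby("participant")["ability"].first().to_dict()
        delt = random_table(
            rng, n=22, cond_means=(1.27, 1.58, 1.58), slope=0.0, noise=0.2
        )
        delt["ability"] = delt["participant"].map(abil)
        delt["quantity"] = "delta"
        res_lam = mixed_anova(lam, "lambda", fixed=("construction", "ability", "interaction"))
        res_del = mixed_anova(delt, "delta", fixed=("construction", "ability", "interaction"))
        p_lam = res_lam.effects.set_index("effect").loc["Ability", "p"]
        p_del = res_del.effects.set_index("effect").loc["Ability", "p"]
        assert p_lam < 0.05
        assert p_del > 0.05


class TestPairwiseContrasts:
    def test_identical_columns_t_zero(self):
        values = {f"P{i}": {c: 1.0 + i for c in CONDS} for i in range(4)}
        out = pairwise_contrasts(make_table(values), "lambda")
        assert np.allclose(out["t"], 0.0)
        assert not out["significant"].any()

    def test_constant_shift_reports_infinite_sentinel(self):
        values = {f"P{i}": {"NoInterp": i + 1.0, "OR": i + 0.0, "OR+SR": i - 1.0} for i in range(4)}
        out = pairwise_contrasts(make_table(values), "lambda").set_index("pair")
        row = out.loc["NoInterp vs OR"]
        assert np.isinf(row.t) and row.t > 0
        assert row.degenerate and row.significant

    def test_antisymmetric_under_pair_swap(self):
        rng = np.random.default_rng(5)
        table = random_table(rng, n=8)
        out = pairwise_contrasts(table, "lambda").set_index("pair")
        swapped = table.copy()
        swapped["condition"] = swapped["condition"].map(
            {"NoInterp": "OR", "OR": "NoInterp", "OR+SR": "OR+SR"}
        )
        out2 = pairwise_contrasts(swapped, "lambda").set_index("pair")
        assert out.loc["NoInterp vs OR", "t"] == pytest.approx(
            -out2.loc["NoInterp vs OR", "t"]
        )

    def test_sign_pattern_matches_generating_order(self):
        rng = np.random.default_rng(6)
        table = random_table(rng, n=10, noise=0.15)
        out = pairwise_contrasts(table, "lambda")
        assert (out["t"] > 0).all()  # NoInterp > OR > OR+SR generating order

    def test_too_few_participants(self):
        values = {"P1": dict(zip(CONDS, (1.0, 2.0, 3.0)))}
        with pytest.raises(EstimationError):
            pairwise_contrasts(make_table(values), "lambda")


class TestTypeIControl:
    def test_label_shuffle_keeps_ability_null(self):
        # permuting ability across participants must not produce effects;
        # seeded permutations, expect >= 93/100 non-significant
        rng = np.random.default_rng(7)
        base = random_table(rng, n=22, slope=0.4, noise=0.25)
        abilities = base.groupby("participant")["ability"].first()
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            perm = rng.permutation(abilities.to_numpy())
            shuffled = base.copy()
            shuffled["ability"] = shuffled["participant"].map(
                dict(zip(abilities.index, perm))
            )
            res = mixed_anova(
                shuffled, "lambda", fixed=("construction", "ability"),
                include_contrasts=False,
            )
            p = res.effects.set_index("effect").loc["Ability", "p"]
            hits += p < 0.05
        assert hits <= 7
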