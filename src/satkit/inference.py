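"""Group-level statistics on empirical asymptotes and fitted SAT parameters.

Condition (Construction) effects on a per-participant quantity — the
empirical asymptote or a fitted lambda/beta/delta — are assessed with a
linear mixed model with random intercepts for participants; a
reading-ability covariate (standardized receptive-vocabulary score) and its
interaction with Construction can be added.  Each fixed effect is reported
as a Wald F with a Satterthwaite-approximated denominator df; for the
balanced random-intercept designs this package produces, the Satterthwaite
df reduce exactly to the classical repeated-measures values, which is the
closed form implemented here.  Pairwise condition contrasts are paired
t-tests on per-participant values, with the field's |t| > 2 significance
convention.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf

from .design import CONSTRUCTIONS
from .errors import DataError, EstimationError
from .fitting import LadderFits

__all__ = [
    "StatResult",
    "mixed_anova",
    "pairwise_contrasts",
    "parameter_table",
]

T_SIGNIFICANT = 2.0


@dataclass
class StatResult:
    """Mixed-model F tests plus pairwise contrasts for one quantity."""

    quantity: str
    effects: pd.DataFrame  # effect, F, df_num, df_den, p
    contrasts: pd.DataFrame  # pair, t, significant, degenerate
    mixed_result: object = None

    def describe(self) -> str:
        lines = [f"Quantity: {self.quantity}"]
        for row in self.effects.itertuples(index=False):
            lines.append(
                f"  {row.effect}: F({row.df_num:.0f}, {row.df_den:.0f}) = "
                f"{row.F:.2f}, p = {row.p:.4g}"
            )
        for row in self.contrasts.itertuples(index=False):
            star = "*" if row.significant else ""
            lines.append(f"  {row.pair}: t = {row.t:.2f}{star}")
        return "\n".join(lines)


def _quantity_frame(table: pd.DataFrame, quantity: str) -> pd.DataFrame:
    need = {"participant", "condition", "quantity", "value"}
    if not need <= set(table.columns):
        raise DataError(f"parameter table needs columns {sorted(need)}")
    df = table[table["quantity"] == quantity].copy()
    if df.empty:
        raise DataError(f"no rows for quantity {quantity!r}")
    dup = df.duplicated(["participant", "condition"])
    if dup.any():
        raise DataError(
            f"multiple rows per participant x condition for quantity {quantity!r}"
        )
    return df


def mixed_anova(
    table: pd.DataFrame,
    quantity: str,
    fixed=("construction",),
    include_contrasts: bool = True,
) -> StatResult:
    """Random-intercept mixed model for one per-participant quantity.

    ``fixed`` is a collection of effect names from {"construction",
    "ability", "interaction"}; ability is z-scored across participants
    before entering the model.  Returns F, numerator df, Satterthwaite
    denominator df and p per fixed effect.
    """
    fixed = {f.lower() for f in fixed}
    unknown = fixed - {"construction", "ability", "interaction"}
    if unknown:
        raise DataError(f"unknown fixed effects {sorted(unknown)}")
    df = _quantity_frame(table, quantity)
    participants = df["participant"].unique()
    n = len(participants)
    if n < 2:
        raise EstimationError("mixed model needs at least 2 participants")
    conditions = [c for c in CONSTRUCTIONS if c in set(df["condition"])]
    if not conditions:
        conditions = sorted(set(df["condition"]))
    J = len(conditions)
    df["condition"] = pd.Categorical(df["condition"], categories=conditions)
    use_ability = "ability" in fixed or "interaction" in fixed
    if use_ability:
        if "ability" not in df.columns or df["ability"].isna().any():
            raise DataError("ability requested but missing from the table")
        per_part = df.groupby("participant")["ability"].first()
        sd = per_part.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise EstimationError("ability has zero variance across participants")
        df["ability_z"] = (df["ability"] - per_part.mean()) / sd
    terms = ["C(condition, Sum)"]
    if use_ability:
        terms.append("ability_z")
    if "interaction" in fixed:
        terms.append("C(condition, Sum):ability_z")
    formula = "value ~ " + " + ".join(terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            mod = smf.mixedlm(formula, df, groups=df["participant"])
            fit = mod.fit(reml=True)
        except Exception as exc:
            raise EstimationError(f"mixed model failed to fit: {exc}") from exc
    fe = fit.fe_params
    cov = fit.cov_params().loc[fe.index, fe.index]
    p_between = 1 + (1 if use_ability else 0)
    df_den_within = (J - 1) * (n - p_between)
    df_den_between = n - p_between
    blocks = [("Construction", "C(condition, Sum)[", df_den_within)]
    if use_ability:
        blocks.append(("Ability", "ability_z", df_den_between))
    if "interaction" in fixed:
        blocks.append(("Construction x Ability", "]:ability_z", df_den_within))
    rows = []
    for label, marker, df_den in blocks:
        if label == "Ability":
            names = [nm for nm in fe.index if nm == "ability_z"]
        elif label == "Construction":
            names = [
                nm for nm in fe.index if nm.startswith("C(condition, Sum)[") and ":" not in nm
            ]
        else:
            names = [nm for nm in fe.index if ":" in nm]
        q = len(names)
        if q == 0:
            continue
        b = fe[names].to_numpy()
        V = cov.loc[names, names].to_numpy()
        try:
            F = float(b @ np.linalg.solve(V, b)) / q
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"singular covariance for effect {label}") from exc
        if df_den <= 0:
            raise EstimationError(f"nonpositive denominator df for {label}")
        p_val = float(stats.f.sf(F, q, df_den))
        # single-df effects use the field's |t| > 2 convention (F > 4)
        significant = F > T_SIGNIFICANT**2 if q == 1 else p_val < 0.05
        rows.append(
            {
                "effect": label,
                "F": F,
                "df_num": q,
                "df_den": df_den,
                "p": p_val,
                "significant": bool(significant),
            }
        )
    contrasts = (
        pairwise_contrasts(table, quantity)
        if include_contrasts and J >= 2
        else pd.DataFrame(columns=["pair", "t", "significant", "degenerate"])
    )
    return StatResult(
        quantity=quantity,
        effects=pd.DataFrame(rows),
        contrasts=contrasts,
        mixed_result=fit,
    )


def pairwise_contrasts(table: pd.DataFrame, quantity: str) -> pd.DataFrame:
    """Paired t-tests between conditions on per-participant values.

    A constant nonzero difference (zero variance) is reported as an
    infinite-t sentinel with ``degenerate=True``; significance uses the
    |t| > 2 convention throughout.
    """
    df = _quantity_frame(table, quantity)
    wide = df.pivot(index="participant", columns="condition", values="value")
    conditions = [c for c in CONSTRUCTIONS if c in wide.columns] + [
        c for c in wide.columns if c not in CONSTRUCTIONS
    ]
    if len(conditions) < 2:
        raise DataError("pairwise contrasts need at least 2 conditions")
    if len(wide) < 2:
        raise EstimationError("pairwise contrasts need at least 2 participants")
    rows = []
    for a, b in itertools.combinations(conditions, 2):
        diffs = (wide[a] - wide[b]).dropna().to_numpy(dtype=float)
        if diffs.size < 2:
            raise EstimationError(f"fewer than 2 paired values for {a} vs {b}")
        mean = float(diffs.mean())
        sd = float(diffs.std(ddof=1))
        degenerate = sd == 0.0
        if degenerate:
            t = 0.0 if mean == 0.0 else float(np.sign(mean) * np.inf)
        else:
            t = mean / (sd / np.sqrt(diffs.size))
        rows.append(
            {
                "pair": f"{a} vs {b}",
                "t": t,
                "significant": bool(abs(t) > T_SIGNIFICANT),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def parameter_table(
    ladder: LadderFits,
    model_name: str,
    abilities: pd.Series | dict | None = None,
    empirical: pd.DataFrame | None = None,
    exclude_flagged: bool = True,
) -> pd.DataFrame:
    """Tidy per-participant parameter table for group-level inference.

    One row per participant x condition x quantity, quantities being the
    fitted ``lambda``/``beta``/``delta`` resolved per condition (and
    ``empirical_asymptote`` rows when an empirical-asymptote table from
    :func:`satkit.scoring.empirical_asymptote_table` is supplied).

    By default participants whose fit is flagged ``asymptote_overestimated``
    are excluded from the fitted-parameter rows — the convention of
    reporting group statistics only over participants the model could fit
    without overestimating their asymptotes.  Empirical-asymptote rows are
    never excluded (they do not depend on the fit).
    """
    rows = []
    for unit in ladder.participants:
        res = ladder.get(unit, model_name)
        if res is None:
            continue
        if exclude_flagged and res.flags.get("asymptote_overestimated"):
            continue
        per = res.params_by_condition
        for cond, r in per.iterrows():
            for quantity, value in (
                ("lambda", r["lam"]),
                ("beta", r["beta"]),
                ("delta", r["delta"]),
            ):
                rows.append(
                    {
                        "participant": unit,
                        "condition": cond,
                        "quantity": quantity,
                        "value": float(value),
                    }
                )
    out = pd.DataFrame(rows)
    if empirical is not None:
        emp = empirical[empirical["participant"] != "average"].copy()
        emp = emp.rename(columns={"empirical_asymptote": "value"})
        emp["quantity"] = "empirical_asymptote"
        out = pd.concat(
            [out, emp[["participant", "condition", "quantity", "value"]]],
            ignore_index=True,
        )
    if abilities is not None:
        ab = pd.Series(abilities)
        out["ability"] = out["participant"].map(ab)
    return out
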