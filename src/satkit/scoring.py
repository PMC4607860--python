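"""Scoring of MR-SAT response streams into d' time courses.

Each trial yields one judgment per response tone: YES, NO, BOTH (both keys
held, i.e. undecided) or NONE (no key held).  Sensitivity at each lag is
the bias-controlled d' = z(hit rate) - z(false-alarm rate), where a hit is
a YES to an acceptable sentence and a false alarm a YES to an unacceptable
one.  BOTH carries 0.5 yes-credit — which is what produces the ~50%
correct-rejection rates at early, undecided lags — and NONE is treated as
missing.  Rates are clipped to [1/(2N), 1 - 1/(2N)] so d' stays finite at
perfect cells.

Control-anomaly trials (anomaly inside the interpolated clause) never enter
d'; their correct-rejection profiles are reported separately as the check
that listeners processed the interpolated material.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignSpec, lag_times
from .errors import DataError
from .simulate import BOTH, NO, NONE, YES

__all__ = [
    "parse_stream",
    "dprime_curves",
    "empirical_asymptote",
    "empirical_asymptote_table",
    "cr_profile",
]

_CREDIT = {YES: 1.0, NO: 0.0, BOTH: 0.5}
#: NO-credit used for correct-rejection profiles
_REJECT_CREDIT = {NO: 1.0, YES: 0.0, BOTH: 0.5}


def parse_stream(stream: pd.DataFrame, spec: DesignSpec, context: str = "") -> list[str]:
    """Decode a key-event stream into one code per tone.

    The key state is sampled at each tone onset ``t_k`` with half-open
    holding intervals: a key is held at ``t_k`` if it went down at or before
    ``t_k`` and up strictly after.  Both keys held -> BOTH, one -> that key,
    none -> NONE.  Event and tone times are compared at microsecond
    tolerance so that rounded on-disk timestamps keep the same boundary
    semantics.
    """
    required = {"time_s", "key", "action"}
    if not required <= set(stream.columns):
        raise DataError(f"event stream needs columns {sorted(required)}")
    t = stream["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise DataError(f"event times not sorted{context and f' ({context})'}")
    intervals: dict[str, list] = {YES: [], NO: []}
    open_down: dict[str, float] = {}
    for row in stream.itertuples(index=False):
        key = row.key
        if key not in intervals:
            raise DataError(f"unknown key {key!r}{context and f' ({context})'}")
        if row.action == "down":
            if key in open_down:
                raise DataError(
                    f"key {key} pressed twice without release at t={row.time_s}"
                    f"{context and f' ({context})'}"
                )
            open_down[key] = float(row.time_s)
        elif row.action == "up":
            if key not in open_down:
                raise DataError(
                    f"key {key} released without press at t={row.time_s}"
                    f"{context and f' ({context})'}"
                )
            intervals[key].append((open_down.pop(key), float(row.time_s)))
        else:
            raise DataError(f"unknown action {row.action!r}")
    for key, down in open_down.items():  # never released: held to the end
        intervals[key].append((down, np.inf))
    codes = []
    tol = 1e-6  # seconds
    for tk in lag_times(spec):
        held = {
            key
            for key, spans in intervals.items()
            if any(d <= tk + tol and u > tk + tol for d, u in spans)
        }
        if held == {YES, NO}:
            codes.append(BOTH)
        elif held == {YES}:
            codes.append(YES)
        elif held == {NO}:
            codes.append(NO)
        else:
            codes.append(NONE)
    return codes


def _lag_columns(trials: pd.DataFrame, spec: DesignSpec) -> list[str]:
    cols = [c for c in trials.columns if c.startswith("lag_")]
    expected = [f"lag_{k}" for k in range(1, spec.n_tones + 1)]
    if cols != expected:
        raise DataError(
            f"trial table has {len(cols)} lag columns, design has {spec.n_tones} tones"
        )
    return cols


def _rate_table(trials: pd.DataFrame, spec: DesignSpec, credit_map) -> pd.DataFrame:
    """Long table of (participant, construction, acceptable, lag, credit, n)."""
    lag_cols = _lag_columns(trials, spec)
    long = trials.melt(
        id_vars=["participant", "construction", "acceptable", "control_anomaly"],
        value_vars=lag_cols,
        var_name="lag",
        value_name="code",
    )
    long["lag"] = long["lag"].str.removeprefix("lag_").astype(int)
    long = long[long["code"] != NONE]
    bad = set(long["code"]) - set(credit_map)
    if bad:
        raise DataError(f"invalid lag codes present: {sorted(bad)}")
    long["credit"] = long["code"].map(credit_map)
    return long


def _clipped_rate(credit_sum, n) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    rate = np.asarray(credit_sum, dtype=float) / n
    lo = 1.0 / (2.0 * n)
    return np.clip(rate, lo, 1.0 - lo)


def dprime_curves(
    trials: pd.DataFrame,
    spec: DesignSpec | None = None,
    correction: str = "clip",
    include_average: bool = True,
    average_method: str = "pool",
) -> pd.DataFrame:
    """Per participant x construction d' time courses (plus the average).

    ``average_method='pool'`` aggregates yes-credit and trial counts across
    participants before the z-transform (the averaged data analysed as a
    single curve set); ``'mean'`` instead averages per-participant d'.

    Returns a tidy frame: participant, condition, lag, lag_time, dprime,
    n_acc, n_unacc.  Control-anomaly trials are excluded.
    """
    spec = spec or DesignSpec()
    if correction != "clip":
        raise DataError(f"unknown edge correction {correction!r}")
    if average_method not in ("pool", "mean"):
        raise DataError(f"unknown average_method {average_method!r}")
    exp = trials[~trials["control_anomaly"].astype(bool)]
    if exp.empty:
        raise DataError("no experimental (non-control) trials to score")
    long = _rate_table(exp, spec, _CREDIT)
    grouped = (
        long.groupby(["participant", "construction", "acceptable", "lag"])
        .agg(credit=("credit", "sum"), n=("credit", "size"))
        .reset_index()
    )
    units = [(p, grouped[grouped["participant"] == p]) for p in grouped["participant"].unique()]
    if include_average and average_method == "pool":
        pooled = (
            grouped.groupby(["construction", "acceptable", "lag"])
            .agg(credit=("credit", "sum"), n=("n", "sum"))
            .reset_index()
        )
        pooled["participant"] = "average"
        units.append(("average", pooled))
    times = lag_times(spec)
    out = []
    for unit, g in units:
        piv_credit = g.pivot_table(
            index=["construction", "lag"], columns="acceptable", values="credit"
        )
        piv_n = g.pivot_table(
            index=["construction", "lag"], columns="acceptable", values="n"
        )
        for col, label in ((True, "acceptable"), (False, "unacceptable")):
            if col not in piv_n.columns or piv_n[col].isna().any():
                missing = (
                    piv_n.index.tolist()
                    if col not in piv_n.columns
                    else piv_n.index[piv_n[col].isna()].tolist()
                )
                raise DataError(
                    f"unit {unit!r}: empty {label} cell(s) at (construction, lag) {missing[:4]}"
                )
        hit = _clipped_rate(piv_credit[True], piv_n[True])
        fa = _clipped_rate(piv_credit[False], piv_n[False])
        d = stats.norm.ppf(hit) - stats.norm.ppf(fa)
        res = piv_n.reset_index()[["construction", "lag"]].copy()
        res["participant"] = unit
        res["dprime"] = d
        res["n_acc"] = piv_n[True].to_numpy()
        res["n_unacc"] = piv_n[False].to_numpy()
        out.append(res)
    curves = pd.concat(out, ignore_index=True)
    curves["lag_time"] = times[curves["lag"].to_numpy() - 1]
    curves = curves.rename(columns={"construction": "condition"})
    curves = curves[
        ["participant", "condition", "lag", "lag_time", "dprime", "n_acc", "n_unacc"]
    ].sort_values(["participant", "condition", "lag"], kind="stable")
    if include_average and average_method == "mean":
        avg = (
            curves.groupby(["condition", "lag", "lag_time"])["dprime"]
            .mean()
            .reset_index()
        )
        avg["participant"] = "average"
        avg["n_acc"] = np.nan
        avg["n_unacc"] = np.nan
        curves = pd.concat([curves, avg], ignore_index=True)
    return curves.reset_index(drop=True)


def empirical_asymptote(curve, m: int = 4) -> float:
    """Mean of the final ``m`` d' values — the empirical asymptote estimate."""
    if isinstance(curve, pd.DataFrame):
        values = curve.sort_values("lag_time")["dprime"].to_numpy(dtype=float)
    else:
        values = np.asarray(curve, dtype=float)
    if m < 1 or m > values.size:
        raise ValueError(f"m={m} outside [1, {values.size}] available lags")
    return float(values[-m:].mean())


def empirical_asymptote_table(curves: pd.DataFrame, m: int = 4) -> pd.DataFrame:
    """Empirical asymptote per participant x condition from a tidy curve table."""
    rows = [
        {
            "participant": p,
            "condition": c,
            "empirical_asymptote": empirical_asymptote(grp, m),
        }
        for (p, c), grp in curves.groupby(["participant", "condition"], sort=False)
    ]
    return pd.DataFrame(rows)


def cr_profile(trials: pd.DataFrame, spec: DesignSpec | None = None) -> pd.DataFrame:
    """Correct-rejection proportion per lag for the two unacceptable groups.

    ``group='control'`` collects control-anomaly trials (anomaly inside the
    interpolated clause); ``group='experimental'`` their construction-matched
    unacceptable counterparts with a sentence-final anomaly.  NO scores 1,
    BOTH 0.5, YES 0; NONE excluded.
    """
    spec = spec or DesignSpec()
    unacc = trials[~trials["acceptable"].astype(bool)].copy()
    ctrl_cons = set(unacc.loc[unacc["control_anomaly"].astype(bool), "construction"])
    if not ctrl_cons:
        raise DataError("no control-anomaly trials present")
    unacc = unacc[unacc["construction"].isin(ctrl_cons)]
    unacc["group"] = np.where(
        unacc["control_anomaly"].astype(bool), "control", "experimental"
    )
    for grp in ("control", "experimental"):
        if not (unacc["group"] == grp).any():
            raise DataError(f"no trials in correct-rejection group {grp!r}")
    long = _rate_table(
        unacc.drop(columns=["construction"]).rename(columns={"group": "construction"}),
        spec,
        _REJECT_CREDIT,
    )
    agg = (
        long.groupby(["construction", "lag"])
        .agg(credit=("credit", "sum"), n=("credit", "size"))
        .reset_index()
        .rename(columns={"construction": "group"})
    )
    agg["cr_rate"] = agg["credit"] / agg["n"]
    times = lag_times(spec)
    agg["lag_time"] = times[agg["lag"].to_numpy() - 1]
    return agg[["group", "lag", "lag_time", "cr_rate", "n"]].sort_values(
        ["group", "lag"], kind="stable"
    ).reset_index(drop=True)
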