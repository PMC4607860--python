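"""Exponential speed–accuracy tradeoff (SAT) model and model specifications.

Accuracy in an MR-SAT task is summarised per response lag as d' and modelled
as an exponential approach to a limit,

    d'(t) = lambda * (1 - exp(-beta * (t - delta)))   for t > delta,
    d'(t) = 0                                         otherwise,

with asymptote ``lambda`` (d' units, representation quality), rate ``beta``
(1/s) and intercept ``delta`` (s, when accuracy departs from chance).  The
two speed parameters (beta, delta) are diagnostic of the retrieval
mechanism, the asymptote of representation availability.

Condition effects are expressed through *parameter sharing*: a
:class:`ModelSpec` such as ``3λ-1β-2δ`` assigns each experimental condition
to a lambda-, beta- and delta-group, so nested model ladders (null model
``1λ-1β-1δ`` up to the saturated ``3λ-3β-3δ``) differ only in their group
maps.  Fit quality is compared with an adjusted R² that penalises the free
parameter count (Judd–McClelland form).

:class:`ExponentialSAT` is the statsmodels-style model object: build it from
a tidy d' curve table plus a :class:`ModelSpec`, call :meth:`~ExponentialSAT.fit`,
and inspect the returned :class:`SATResults`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONSTRUCTIONS
from .errors import ComparisonError, ConfigError, DataError, EstimationError

__all__ = [
    "SATParams",
    "ModelSpec",
    "parse_model_spec",
    "evaluate_sat",
    "objective_sse",
    "adjusted_r2",
    "ExponentialSAT",
    "SATResults",
]


@dataclass(frozen=True)
class SATParams:
    """One condition's asymptote / rate / intercept triple."""

    lam: float
    beta: float
    delta: float

    def __post_init__(self):
        if self.lam < 0:
            raise ConfigError(f"asymptote lambda must be >= 0, got {self.lam}")
        if self.beta <= 0:
            raise ConfigError(f"rate beta must be > 0, got {self.beta}")
        if self.delta < 0:
            raise ConfigError(f"intercept delta must be >= 0, got {self.delta}")


def evaluate_sat(params: SATParams | tuple, t) -> np.ndarray | float:
    """Evaluate the exponential SAT function at time(s) ``t`` (seconds).

    Returns exactly 0 for ``t <= delta``; continuous at ``t = delta``.
    """
    if isinstance(params, SATParams):
        lam, beta, delta = params.lam, params.beta, params.delta
    else:
        lam, beta, delta = params
    t = np.asarray(t, dtype=float)
    out = np.where(t > delta, lam * -np.expm1(-beta * (t - delta)), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


_SPEC_RE = re.compile(
    r"^\s*(\d+)\s*(?:λ|lambda|l)\s*-\s*(\d+)\s*(?:β|beta|b)\s*-\s*(\d+)\s*(?:δ|delta|d)\s*$",
    re.IGNORECASE,
)


@dataclass(frozen=True)
class ModelSpec:
    """A parameter-sharing scheme over experimental conditions.

    ``lambda_map`` / ``beta_map`` / ``delta_map`` assign each condition a
    1-based, contiguous group index; conditions sharing a group share the
    parameter.  The free-parameter count ``k`` is the total number of
    groups.
    """

    name: str
    conditions: tuple = tuple(CONSTRUCTIONS)
    lambda_map: tuple = (1, 1, 1)
    beta_map: tuple = (1, 1, 1)
    delta_map: tuple = (1, 1, 1)

    def __post_init__(self):
        for label, m in self._maps().items():
            if len(m) != len(self.conditions):
                raise ConfigError(
                    f"{label} maps {len(m)} conditions; spec has {len(self.conditions)}"
                )
            groups = sorted(set(m))
            if groups != list(range(1, len(groups) + 1)):
                raise ConfigError(
                    f"{label} group indices must be contiguous from 1, got {sorted(set(m))}"
                )

    def _maps(self) -> dict:
        return {
            "lambda_map": self.lambda_map,
            "beta_map": self.beta_map,
            "delta_map": self.delta_map,
        }

    @property
    def n_lambda(self) -> int:
        return max(self.lambda_map)

    @property
    def n_beta(self) -> int:
        return max(self.beta_map)

    @property
    def n_delta(self) -> int:
        return max(self.delta_map)

    @property
    def k(self) -> int:
        """Free-parameter count: total number of lambda/beta/delta groups."""
        return self.n_lambda + self.n_beta + self.n_delta

    @property
    def param_names(self) -> list[str]:
        return (
            [f"lambda{g}" for g in range(1, self.n_lambda + 1)]
            + [f"beta{g}" for g in range(1, self.n_beta + 1)]
            + [f"delta{g}" for g in range(1, self.n_delta + 1)]
        )

    def unpack(self, theta) -> dict[str, SATParams]:
        """Resolve a theta vector into per-condition parameter triples."""
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.k:
            raise ConfigError(f"theta has {theta.size} entries, spec needs k={self.k}")
        lams = theta[: self.n_lambda]
        betas = theta[self.n_lambda : self.n_lambda + self.n_beta]
        deltas = theta[self.n_lambda + self.n_beta :]
        out = {}
        for i, cond in enumerate(self.conditions):
            out[cond] = SATParams(
                lam=float(lams[self.lambda_map[i] - 1]),
                beta=float(betas[self.beta_map[i] - 1]),
                delta=float(deltas[self.delta_map[i] - 1]),
            )
        return out

    def pack(self, per_condition: dict) -> np.ndarray:
        """Inverse of :meth:`unpack`; values within a group must agree."""
        theta = np.full(self.k, np.nan)
        for i, cond in enumerate(self.conditions):
            p = per_condition[cond]
            lam, beta, delta = (
                (p.lam, p.beta, p.delta) if isinstance(p, SATParams) else p
            )
            for offset, g, val in (
                (0, self.lambda_map[i], lam),
                (self.n_lambda, self.beta_map[i], beta),
                (self.n_lambda + self.n_beta, self.delta_map[i], delta),
            ):
                slot = offset + g - 1
                if not np.isnan(theta[slot]) and not np.isclose(theta[slot], val):
                    raise ConfigError(
                        f"conditions sharing a group disagree on its value near {cond}"
                    )
                theta[slot] = val
        return theta


def _two_group_map(conditions) -> tuple:
    """Default two-group preset: NoInterp alone vs everything interpolated."""
    if "NoInterp" not in conditions:
        raise ConfigError(
            "two-group preset needs a 'NoInterp' condition; supply an explicit grouping"
        )
    return tuple(1 if c == "NoInterp" else 2 for c in conditions)


def parse_model_spec(
    name: str,
    conditions=tuple(CONSTRUCTIONS),
    lambda_map=None,
    beta_map=None,
    delta_map=None,
) -> ModelSpec:
    """Build a :class:`ModelSpec` from a name like ``"3λ-1β-2δ"``.

    ASCII spellings (``3L-1B-2D``, ``3lambda-1beta-2delta``) are accepted.
    Counts of 1 share one group across all conditions; counts equal to the
    number of conditions give each its own group; a count of 2 applies the
    {NoInterp} vs {interpolated} preset unless an explicit map overrides it.
    """
    m = _SPEC_RE.match(name)
    if not m:
        raise ConfigError(f"model name {name!r} does not match '<a>λ-<b>β-<c>δ'")
    counts = tuple(int(g) for g in m.groups())
    n = len(conditions)
    maps = [lambda_map, beta_map, delta_map]
    for j, count in enumerate(counts):
        if count < 1 or count > n:
            raise ConfigError(
                f"group count {count} in {name!r} exceeds the {n} conditions"
            )
        if maps[j] is None:
            if count == 1:
                maps[j] = tuple(1 for _ in conditions)
            elif count == n:
                maps[j] = tuple(range(1, n + 1))
            elif count == 2:
                maps[j] = _two_group_map(conditions)
            else:
                raise ConfigError(
                    f"no default grouping for {count} groups over {n} conditions; "
                    "supply an explicit map"
                )
        elif max(maps[j]) != count:
            raise ConfigError(
                f"explicit map {maps[j]} has {max(maps[j])} groups, name says {count}"
            )
    canonical = f"{counts[0]}λ-{counts[1]}β-{counts[2]}δ"
    return ModelSpec(
        name=canonical,
        conditions=tuple(conditions),
        lambda_map=tuple(maps[0]),
        beta_map=tuple(maps[1]),
        delta_map=tuple(maps[2]),
    )


def adjusted_r2(obs, pred, k: int) -> float:
    """Parameter-adjusted proportion of variance accounted for.

    ``1 - [SS_res/(n-k)] / [SS_tot/(n-1)]`` with SS_tot about the mean of
    the observations.  Can be negative for models worse than the mean;
    never exceeds 1.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise DataError(f"obs and pred shapes differ: {obs.shape} vs {pred.shape}")
    n = obs.size
    if n <= k:
        raise EstimationError(f"adjusted R2 needs n > k, got n={n}, k={k}")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise EstimationError("observations have zero variance; adjusted R2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - (ss_res / (n - k)) / (ss_tot / (n - 1))


class ExponentialSAT:
    """Exponential SAT model bound to one unit's d' curves.

    Parameters
    ----------
    data :
        Tidy DataFrame with columns ``condition``, ``lag_time`` and
        ``dprime`` for a single analysis unit (one participant, or the
        averaged data).  Optionally a ``weight`` column.
    spec :
        The parameter-sharing :class:`ModelSpec` to estimate.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        required = {"condition", "lag_time", "dprime"}
        missing = required - set(data.columns)
        if missing:
            raise DataError(f"curve data missing columns: {sorted(missing)}")
        present = set(data["condition"])
        absent = [c for c in spec.conditions if c not in present]
        if absent:
            raise DataError(f"curve data has no rows for conditions: {absent}")
        extra = present - set(spec.conditions)
        if extra:
            raise DataError(f"curve data has unmapped conditions: {sorted(extra)}")
        data = data.sort_values(["condition", "lag_time"], kind="stable")
        self.data = data.reset_index(drop=True)
        self.spec = spec
        cond_index = {c: i for i, c in enumerate(spec.conditions)}
        ci = self.data["condition"].map(cond_index).to_numpy()
        self._t = self.data["lag_time"].to_numpy(dtype=float)
        self._y = self.data["dprime"].to_numpy(dtype=float)
        if "weight" in self.data.columns:
            self._w = self.data["weight"].to_numpy(dtype=float)
        else:
            self._w = None
        # per-point group indices (0-based) into the theta vector
        lam_ix = np.asarray(spec.lambda_map, dtype=int) - 1
        beta_ix = np.asarray(spec.beta_map, dtype=int) - 1 + spec.n_lambda
        del_ix = np.asarray(spec.delta_map, dtype=int) - 1 + spec.n_lambda + spec.n_beta
        self._lam_ix = lam_ix[ci]
        self._beta_ix = beta_ix[ci]
        self._del_ix = del_ix[ci]

    @classmethod
    def from_dataframe(
        cls, curves: pd.DataFrame, spec: ModelSpec, participant=None
    ) -> "ExponentialSAT":
        """Select one participant (or ``"average"``) from a multi-unit table."""
        if participant is not None and "participant" in curves.columns:
            curves = curves[curves["participant"] == participant]
            if curves.empty:
                raise DataError(f"no curve rows for participant {participant!r}")
        return cls(curves, spec)

    @property
    def nobs(self) -> int:
        return self._y.size

    @property
    def endog(self) -> np.ndarray:
        return self._y

    def predict(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        lam = theta[self._lam_ix]
        beta = theta[self._beta_ix]
        delta = theta[self._del_ix]
        dt = self._t - delta
        return np.where(dt > 0, lam * -np.expm1(-beta * dt), 0.0)

    def sse(self, theta) -> float:
        r = self._y - self.predict(theta)
        if self._w is not None:
            return float(np.sum(self._w * r * r))
        return float(np.dot(r, r))

    def sse_grad(self, theta):
        """Objective and its analytic gradient (for gradient-based solvers).

        The SAT function is flat in all parameters wherever ``t <= delta``,
        so those points contribute zero gradient.
        """
        theta = np.asarray(theta, dtype=float)
        lam = theta[self._lam_ix]
        beta = theta[self._beta_ix]
        delta = theta[self._del_ix]
        dt = self._t - delta
        pos = dt > 0
        e = np.exp(-beta * np.where(pos, dt, 0.0))
        pred = np.where(pos, lam * (1.0 - e), 0.0)
        r = pred - self._y
        w = self._w if self._w is not None else 1.0
        sse = float(np.sum(w * r * r))
        common = 2.0 * w * r
        k = len(theta)
        g_lam = common * np.where(pos, 1.0 - e, 0.0)
        g_beta = common * np.where(pos, lam * dt * e, 0.0)
        g_delta = common * np.where(pos, -lam * beta * e, 0.0)
        grad = (
            np.bincount(self._lam_ix, weights=g_lam, minlength=k)
            + np.bincount(self._beta_ix, weights=g_beta, minlength=k)
            + np.bincount(self._del_ix, weights=g_delta, minlength=k)
        )
        return sse, grad

    def fit(self, config=None, seed: int = 0):
        """Fit with the multi-start optimizer portfolio; see :mod:`satkit.fitting`."""
        from .fitting import FitConfig, fit_model

        cfg = config or FitConfig(seed=seed)
        return fit_model(self, cfg)

    def results(self, theta, run_log=None) -> "SATResults":
        return SATResults(self, np.asarray(theta, dtype=float), run_log=run_log)


def objective_sse(theta, spec: ModelSpec, curves: pd.DataFrame, fit_lags=None) -> float:
    """Least-squares objective: sum over conditions and included lag times of
    squared (observed d' - model d'), parameters resolved through the spec's
    group maps.  ``fit_lags`` optionally restricts to a subset of 1-based
    lag indices (lag order within each condition's sorted times)."""
    if fit_lags is not None:
        keep = []
        for _, grp in curves.groupby("condition", sort=False):
            grp = grp.sort_values("lag_time")
            sel = grp.iloc[[i - 1 for i in fit_lags]]
            keep.append(sel)
        curves = pd.concat(keep, ignore_index=True)
    return ExponentialSAT(curves, spec).sse(theta)


class SATResults:
    """Fit results for an :class:`ExponentialSAT` model.

    Carries the estimated theta, per-name parameter Series, SSE, adjusted
    R², the optimizer run log and validity flags.
    """

    def __init__(self, model: ExponentialSAT, theta: np.ndarray, run_log=None):
        self.model = model
        self.theta = np.asarray(theta, dtype=float)
        self.spec = model.spec
        self.params = pd.Series(self.theta, index=self.spec.param_names)
        self.sse = model.sse(self.theta)
        self.nobs = model.nobs
        self.df_resid = self.nobs - self.spec.k
        try:
            self.rsquared_adj = adjusted_r2(model.endog, self.fittedvalues, self.spec.k)
        except EstimationError:
            # e.g. identically-zero curves: the statistic is undefined but
            # the fit itself is still valid
            self.rsquared_adj = float("nan")
        self.run_log = run_log if run_log is not None else pd.DataFrame()
        self.flags: dict = {}

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.theta)

    @property
    def params_by_condition(self) -> pd.DataFrame:
        per = self.spec.unpack(self.theta)
        return pd.DataFrame(
            {
                "condition": list(per),
                "lam": [p.lam for p in per.values()],
                "beta": [p.beta for p in per.values()],
                "delta": [p.delta for p in per.values()],
            }
        ).set_index("condition")

    def predict(self, times, condition: str) -> np.ndarray:
        """Model d' at arbitrary times for one condition."""
        per = self.spec.unpack(self.theta)
        if condition not in per:
            raise DataError(f"unknown condition {condition!r}")
        return evaluate_sat(per[condition], times)

    def compare(self, other: "SATResults") -> float:
        """Adjusted-R² difference (self as the smaller, nested model)."""
        if self.spec.k >= other.spec.k:
            raise ComparisonError(
                f"compare expects k(small) < k(large); got {self.spec.k} vs {other.spec.k}"
            )
        return other.rsquared_adj - self.rsquared_adj

    def summary(self) -> str:
        lines = [
            f"Exponential SAT model {self.spec.name}",
            f"  conditions: {', '.join(self.spec.conditions)}",
            f"  n obs: {self.nobs}   free parameters k: {self.spec.k}",
            f"  SSE: {self.sse:.6g}   adjusted R2: {self.rsquared_adj:.4f}",
            "",
            "  parameter estimates:",
        ]
        for name, value in self.params.items():
            lines.append(f"    {name:<10s} {value:10.4f}")
        lines.append("")
        lines.append("  per condition (lambda / beta / delta):")
        for cond, row in self.params_by_condition.iterrows():
            lines.append(
                f"    {cond:<10s} {row['lam']:7.3f} {row['beta']:7.3f} {row['delta']:7.3f}"
            )
        if self.flags:
            lines.append("")
            lines.append(f"  flags: {self.flags}")
        return "\n".join(lines)

    def __repr__(self):  # pragma: no cover - cosmetic
        return (
            f"<SATResults {self.spec.name} sse={self.sse:.4g} "
            f"adjR2={self.rsquared_adj:.4f}>"
        )
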