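"""Multi-start bounded optimization for exponential SAT models.

The published workflow selected the best of four optimization algorithms,
each restarted ten times from random starting values; this module keeps
that contract as a configurable *portfolio*: at least two distinct
algorithm families, each run ``restarts`` times from uniform-within-bounds
seeded starts, with the overall arg-min of the least-squares objective kept
(ties broken by lower SSE, then fewer iterations, then run order) and a
final high-precision polish from the winner.

Validity of a fit is assessed the way SAT practitioners do informally: a
fitted asymptote far above its condition's empirical asymptote (mean of the
last four d' values), or parameters pinned at a box bound, flag the fit as
suspect.  Per-participant per-model ladders propagate such failures as
recorded exclusions instead of aborting.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ConfigError, DataError, FitFailureError
from .model import ExponentialSAT, ModelSpec, SATResults
from .scoring import empirical_asymptote

__all__ = [
    "FitConfig",
    "fit_model",
    "check_asymptotes",
    "fit_ladder",
    "LadderFits",
]

DEFAULT_BOUNDS = {
    "lambda": (0.0, 6.0),
    "beta": (0.05, 6.0),
    "delta": (0.0, 3.0),
}

#: algorithm portfolio; all are run through scipy.optimize.minimize
DEFAULT_PORTFOLIO = ("L-BFGS-B", "Powell", "TNC", "Nelder-Mead")


@dataclass(frozen=True)
class FitConfig:
    """Optimizer-portfolio configuration.

    ``bounds`` gives the box per parameter kind (d' units for lambda, 1/s
    for beta, seconds for delta).  A stricter asymptote floor (e.g. 0.4 d',
    seen as an exact repeated value in published individual fits) can be
    imposed by overriding ``bounds['lambda']``.
    """

    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    restarts: int = 10
    algorithms: tuple = DEFAULT_PORTFOLIO
    seed: int = 0
    ftol: float = 1e-10
    polish: bool = True
    informed_start: bool = True
    asymptote_margin: float = 1.0
    bound_tol: float = 1e-3

    def __post_init__(self):
        if self.restarts < 1:
            raise ConfigError("restarts must be >= 1")
        if len(self.algorithms) < 1:
            raise ConfigError("portfolio must contain at least one algorithm")
        for kind in ("lambda", "beta", "delta"):
            lo, hi = self.bounds[kind]
            if not lo < hi:
                raise ConfigError(f"bounds for {kind} must satisfy lower < upper")

    def bounds_vector(self, spec: ModelSpec) -> list[tuple]:
        return (
            [tuple(self.bounds["lambda"])] * spec.n_lambda
            + [tuple(self.bounds["beta"])] * spec.n_beta
            + [tuple(self.bounds["delta"])] * spec.n_delta
        )


def _informed_start(model: ExponentialSAT, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Data-driven start: empirical asymptotes for lambda groups, the time
    the observed curve reaches ~20% of its late level for delta groups, and
    a mid-range rate.  Clipped into the box."""
    spec = model.spec
    data = model.data
    emp = {}
    rise = {}
    for cond in spec.conditions:
        sub = data[data["condition"] == cond].sort_values("lag_time")
        y = sub["dprime"].to_numpy(dtype=float)
        t = sub["lag_time"].to_numpy(dtype=float)
        m = min(4, y.size)
        emp[cond] = float(y[-m:].mean())
        level = max(emp[cond], 1e-6) * 0.2
        above = np.nonzero(y > level)[0]
        rise[cond] = float(t[above[0]]) if above.size else float(t[-1])
    theta = np.empty(spec.k)
    for g in range(1, spec.n_lambda + 1):
        conds = [c for c, gg in zip(spec.conditions, spec.lambda_map) if gg == g]
        theta[g - 1] = np.mean([emp[c] for c in conds])
    theta[spec.n_lambda : spec.n_lambda + spec.n_beta] = 1.0
    off = spec.n_lambda + spec.n_beta
    for g in range(1, spec.n_delta + 1):
        conds = [c for c, gg in zip(spec.conditions, spec.delta_map) if gg == g]
        theta[off + g - 1] = np.mean([rise[c] for c in conds])
    return np.clip(theta, lo, hi)


def _run_one(model: ExponentialSAT, x0, bounds, method: str, ftol: float):
    fun = model.sse
    kwargs = {"method": method, "bounds": bounds}
    if method in ("L-BFGS-B", "TNC"):
        fun = model.sse_grad
        kwargs["jac"] = True
        kwargs["options"] = {"ftol": ftol}
    elif method == "Powell":
        kwargs["options"] = {"ftol": ftol, "xtol": max(1e-8, 1e3 * ftol)}
    elif method == "Nelder-Mead":
        kwargs["options"] = {"fatol": max(ftol, 1e-12), "xatol": 1e-8, "maxiter": 2000}
    res = optimize.minimize(fun, x0, **kwargs)
    x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
    return x, float(model.sse(x)), int(res.get("nit", 0) or 0), bool(res.success)


def fit_model(
    model_or_curves,
    spec: ModelSpec | None = None,
    config: FitConfig | None = None,
    unit=None,
) -> SATResults:
    """Fit an exponential SAT model with the multi-start portfolio.

    Accepts either a prepared :class:`ExponentialSAT` or a tidy curve
    DataFrame plus a :class:`ModelSpec`.  Deterministic given (data, spec,
    config): the starting points depend only on ``config.seed``.
    """
    if isinstance(model_or_curves, ExponentialSAT):
        model = model_or_curves
        if config is None and isinstance(spec, FitConfig):  # fit_model(m, cfg)
            config = spec
            spec = None
    else:
        if spec is None:
            raise ConfigError("a ModelSpec is required when passing raw curves")
        model = ExponentialSAT.from_dataframe(model_or_curves, spec, participant=unit)
    cfg = config or FitConfig()
    bounds = cfg.bounds_vector(model.spec)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    rng = np.random.default_rng(cfg.seed)
    n_random = len(cfg.algorithms) * cfg.restarts
    starts = lo + (hi - lo) * rng.random((n_random, len(bounds)))
    informed = _informed_start(model, lo, hi) if cfg.informed_start else None
    run_plan = []
    si = 0
    for method in cfg.algorithms:
        for r in range(cfg.restarts):
            run_plan.append((method, str(r), starts[si]))
            si += 1
        if informed is not None:
            run_plan.append((method, "informed", informed))
    log_rows = []
    best = None  # (sse, nit, run_index, x)
    for run, (method, label, x0) in enumerate(run_plan):
        try:
            x, sse, nit, ok = _run_one(model, x0, bounds, method, cfg.ftol)
        except Exception as exc:  # optimizer blow-up counts as a failed run
            log_rows.append(
                {
                    "algorithm": method,
                    "restart": label,
                    "start": x0.copy(),
                    "sse": np.inf,
                    "nit": 0,
                    "converged": False,
                    "error": str(exc),
                }
            )
            continue
        log_rows.append(
            {
                "algorithm": method,
                "restart": label,
                "start": x0.copy(),
                "sse": sse,
                "nit": nit,
                "converged": ok,
                "error": "",
            }
        )
        if np.isfinite(sse):
            key = (sse, nit, run)
            if best is None or key < (best[0], best[1], best[2]):
                best = (sse, nit, run, x)
    run_log = pd.DataFrame(log_rows)
    if best is None:
        raise FitFailureError("no optimization run produced a finite objective", run_log)
    x_best = best[3]
    if cfg.polish:
        try:
            res = optimize.minimize(
                model.sse_grad,
                x_best,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 2000},
            )
            x_pol = np.clip(res.x, lo, hi)
            if model.sse(x_pol) <= best[0]:
                x_best = x_pol
        except Exception:
            pass
    results = model.results(x_best, run_log=run_log)
    check_asymptotes(results, config=cfg)
    return results


def check_asymptotes(
    fit: SATResults,
    curves: pd.DataFrame | None = None,
    config: FitConfig | None = None,
) -> dict:
    """Set validity flags on a fit.

    ``asymptote_overestimated``: some fitted asymptote exceeds its
    condition's empirical asymptote (mean of the last four observed d'
    values) by more than ``asymptote_margin``, or sits at the upper bound.
    ``at_bound``: any parameter within ``bound_tol`` of a box bound.
    """
    cfg = config or FitConfig()
    data = curves if curves is not None else fit.model.data
    bounds = cfg.bounds_vector(fit.spec)
    theta = fit.theta
    at_bound = any(
        min(abs(v - b[0]), abs(v - b[1])) <= cfg.bound_tol
        for v, b in zip(theta, bounds)
    )
    lam_hi = cfg.bounds["lambda"][1]
    per = fit.spec.unpack(theta)
    over = False
    for cond, p in per.items():
        sub = data[data["condition"] == cond]
        if sub.empty:
            raise DataError(f"no curve rows for condition {cond!r}")
        m = min(4, len(sub))
        emp = empirical_asymptote(sub, m=m)
        if p.lam > emp + cfg.asymptote_margin or p.lam >= lam_hi - cfg.bound_tol:
            over = True
    flags = {"asymptote_overestimated": over, "at_bound": at_bound}
    fit.flags.update(flags)
    return flags


class LadderFits:
    """Results of fitting a model ladder per unit (participants + average).

    ``results[unit][model_name]`` holds the :class:`SATResults`; failed
    fits are recorded in ``failures`` as (unit, model_name, reason) without
    aborting the ladder.
    """

    def __init__(self):
        self.results: dict[str, dict[str, SATResults]] = {}
        self.failures: list[tuple] = []

    def add(self, unit, name, res):
        self.results.setdefault(unit, {})[name] = res

    @property
    def units(self) -> list:
        return list(self.results)

    @property
    def participants(self) -> list:
        return [u for u in self.results if u != "average"]

    def get(self, unit, name) -> SATResults | None:
        return self.results.get(unit, {}).get(name)

    def to_frame(self) -> pd.DataFrame:
        """One tidy row per (unit, model, parameter) plus summary rows."""
        rows = []
        for unit, per_model in self.results.items():
            for name, res in per_model.items():
                for pname, value in res.params.items():
                    rows.append(
                        {
                            "participant": unit,
                            "model": name,
                            "kind": "parameter",
                            "name": pname,
                            "value": value,
                        }
                    )
                rows.append(
                    {
                        "participant": unit,
                        "model": name,
                        "kind": "summary",
                        "name": "sse",
                        "value": res.sse,
                    }
                )
                rows.append(
                    {
                        "participant": unit,
                        "model": name,
                        "kind": "summary",
                        "name": "adj_r2",
                        "value": res.rsquared_adj,
                    }
                )
        return pd.DataFrame(rows)


def _unit_seed(base_seed: int, unit, name: str) -> int:
    # stable, order-independent per-(unit, model) substream; keep < 2**31
    return (zlib.crc32(f"{unit}|{name}".encode()) ^ (base_seed & 0x7FFFFFFF)) & 0x7FFFFFFF


def fit_ladder(
    curves: pd.DataFrame,
    specs: list[ModelSpec],
    config: FitConfig | None = None,
    fit_lags=None,
) -> LadderFits:
    """Fit every spec to every unit in a tidy multi-unit curve table.

    ``fit_lags`` optionally restricts fitting to a subset of 1-based lag
    indices (default: all lags present; the pipeline passes lags 2..n to
    drop the pre-onset tone).  Seeds are derived per (unit, model) from
    ``config.seed`` so ladders are reproducible and order-invariant.
    """
    cfg = config or FitConfig()
    out = LadderFits()
    if "participant" not in curves.columns:
        curves = curves.assign(participant="average")
    if fit_lags is not None:
        if "lag" not in curves.columns:
            raise DataError("fit_lags given but curve table has no 'lag' column")
        curves = curves[curves["lag"].isin(list(fit_lags))]
    for unit in curves["participant"].unique():
        sub = curves[curves["participant"] == unit]
        for spec in specs:
            run_cfg = replace(cfg, seed=_unit_seed(cfg.seed, unit, spec.name))
            try:
                res = fit_model(sub, spec, run_cfg)
            except (FitFailureError, DataError) as exc:
                out.failures.append((unit, spec.name, str(exc)))
                continue
            res.unit = unit
            out.add(unit, spec.name, res)
    return out
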