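"""Generative model of MR-SAT response streams.

The simulator emulates the statistical structure the downstream analysis
assumes: each participant carries a latent exponential discriminability
curve d(t) per construction, and responds at every tone under equal-variance
signal detection with symmetric criterion placement,

    P(YES | acceptable)   = Phi(d(t)/2 - c)
    P(YES | unacceptable) = Phi(-d(t)/2 - c),

which inverts exactly to d' when hits and false alarms are z-transformed.
Before the latent curve rises above zero the simulated listener holds both
response keys ("undecided"), mirroring the task instruction to press both
buttons until a decision is reached.  Control-anomaly trials (anomaly inside
the interpolated clause) follow a curve with a scaled-down asymptote, so
their correct rejections grow exponentially but stay below the experimental
conditions.

Individual differences enter through a receptive-vocabulary ability score:
standardized ability shifts the asymptote only (``ability_slope_lambda``),
matching the empirical finding that ability affects representation quality
but not retrieval speed.

All randomness flows from one integer root seed; participant- and
trial-level substreams are derived from (seed, participant index, trial
index), so enlarging a cohort never reshuffles existing trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import EXP2_AVG_3L1B2D, VOCABULARY_PRIOR
from .design import DesignSpec, build_design, lag_times
from .errors import ConfigError, DataError
from .model import SATParams, parse_model_spec

__all__ = [
    "GenerativeParams",
    "CohortSpec",
    "default_true_params",
    "simulate_trial_lags",
    "render_stream",
    "sample_participants",
    "simulate_cohort",
]

YES, NO, BOTH, NONE = "YES", "NO", "BOTH", "NONE"


def default_true_params() -> dict[str, SATParams]:
    """Community-cohort averaged-data estimates as the generating truth."""
    spec = parse_model_spec(EXP2_AVG_3L1B2D["model"])
    return spec.unpack(EXP2_AVG_3L1B2D["theta"])


@dataclass(frozen=True)
class GenerativeParams:
    """One simulated participant's generative state.

    ``params`` maps construction -> true :class:`SATParams`; ``ability`` is
    the raw vocabulary scaled score, standardized against the cohort prior
    before the asymptote slope is applied.
    """

    params: dict = field(default_factory=default_true_params)
    criterion: float = 0.0
    ability: float = VOCABULARY_PRIOR["mean"]
    ability_slope_lambda: float = 0.0
    switch_prob: float = 0.0
    control_lambda_fraction: float = 0.8
    decision_delay_sigma: float | None = None
    trials_per_cell: int = 48

    def __post_init__(self):
        if not 0.0 <= self.switch_prob <= 0.5:
            raise ConfigError(f"switch_prob must lie in [0, 0.5], got {self.switch_prob}")
        if not 0.0 <= self.control_lambda_fraction <= 1.0:
            raise ConfigError("control_lambda_fraction must lie in [0, 1]")
        for cons, p in self.params.items():
            if not isinstance(p, SATParams):
                raise ConfigError(f"params[{cons!r}] must be SATParams")

    @property
    def ability_z(self) -> float:
        return (self.ability - VOCABULARY_PRIOR["mean"]) / VOCABULARY_PRIOR["sd"]

    def curve_params(self, construction: str, control_anomaly: bool = False) -> SATParams:
        """Effective latent curve for a trial of the given kind."""
        try:
            base = self.params[construction]
        except KeyError:
            raise DataError(f"unknown construction {construction!r}") from None
        lam = max(0.0, base.lam + self.ability_slope_lambda * self.ability_z)
        if control_anomaly:
            lam *= self.control_lambda_fraction
        return SATParams(lam=lam, beta=base.beta, delta=base.delta)


def _latent_curve(p: SATParams, delta_shift: float, times: np.ndarray) -> np.ndarray:
    dt = times - (p.delta + delta_shift)
    return np.where(dt > 0, p.lam * -np.expm1(-p.beta * dt), 0.0)


def simulate_trial_lags(gp: GenerativeParams, trial, spec: DesignSpec, seed) -> list[str]:
    """Simulate the per-lag response codes of one trial.

    ``trial`` is any mapping with ``construction``, ``acceptable`` and
    ``control_anomaly`` entries.  While the latent curve is exactly zero the
    emitted code is BOTH; afterwards a YES/NO decision is drawn per lag from
    the SDT response rule, optionally flipped with ``switch_prob``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = gp.curve_params(trial["construction"], bool(trial["control_anomaly"]))
    delay = 0.0
    if gp.decision_delay_sigma is not None:
        delay = float(rng.lognormal(mean=np.log(0.1), sigma=gp.decision_delay_sigma))
    times = lag_times(spec)
    d = _latent_curve(p, delay, times)
    acceptable = bool(trial["acceptable"])
    sign = 0.5 if acceptable else -0.5
    p_yes = stats.norm.cdf(sign * d - gp.criterion)
    says_yes = rng.random(times.size) < p_yes
    if gp.switch_prob > 0:
        flips = rng.random(times.size) < gp.switch_prob
        says_yes = says_yes ^ flips
    undecided = d <= 0
    return [
        BOTH if und else (YES if sy else NO)
        for und, sy in zip(undecided, says_yes)
    ]


def render_stream(lag_codes, spec: DesignSpec) -> pd.DataFrame:
    """Turn per-lag codes into a key-press event stream.

    Emits ``(time_s, key, action)`` rows such that at each tone time exactly
    the keys implied by that lag's code are held (a key is held at ``t`` if
    its down event is at or before ``t`` and its up event is strictly
    after).  All held keys are released when the response window closes,
    ``response_period`` seconds after the first tone.  Round-trips with
    :func:`satkit.scoring.parse_stream`.
    """
    lag_codes = list(lag_codes)
    if len(lag_codes) != spec.n_tones:
        raise DataError(
            f"got {len(lag_codes)} lag codes for a design with {spec.n_tones} tones"
        )
    wanted = {YES: {YES}, NO: {NO}, BOTH: {YES, NO}, NONE: set()}
    events = []
    held: set = set()
    times = lag_times(spec)
    for t, code in zip(times, lag_codes):
        if code not in wanted:
            raise DataError(f"invalid lag code {code!r}")
        target = wanted[code]
        for key in sorted(held - target):
            events.append((float(t), key, "up"))
        for key in sorted(target - held):
            events.append((float(t), key, "down"))
        held = set(target)
    if lag_codes:
        t_end = float(times[0] + spec.response_period)
        for key in sorted(held):
            events.append((t_end, key, "up"))
    return pd.DataFrame(events, columns=["time_s", "key", "action"])


@dataclass(frozen=True)
class CohortSpec:
    """Population-level generative settings for a simulated cohort.

    Defaults define the study conditions of the 22-participant community
    cohort: generating truth = its averaged-data 3λ-1β-2δ estimates, a
    truncated-normal vocabulary prior, ability shifting the asymptote only
    (0.3 d' per ability SD), moderate between-participant heterogeneity in
    asymptote, rate and intercept, and 48 trials per design cell (each
    participant hears all four lists over four sessions).
    """

    n_participants: int = 22
    true_params: dict = field(default_factory=default_true_params)
    ability_slope_lambda: float = 0.3
    lambda_sd: float = 0.3
    beta_log_sd: float = 0.25
    delta_sd: float = 0.2
    criterion: float = 0.0
    switch_prob: float = 0.0
    control_lambda_fraction: float = 0.8
    decision_delay_sigma: float | None = None
    trials_per_cell: int = 48

    def __post_init__(self):
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if self.trials_per_cell < 1:
            raise ConfigError("trials_per_cell must be >= 1")
        if min(self.lambda_sd, self.beta_log_sd, self.delta_sd) < 0:
            raise ConfigError("heterogeneity standard deviations must be >= 0")


def _sample_ability(rng: np.random.Generator) -> float:
    pr = VOCABULARY_PRIOR
    a = (pr["low"] - pr["mean"]) / pr["sd"]
    b = (pr["high"] - pr["mean"]) / pr["sd"]
    return float(stats.truncnorm.rvs(a, b, loc=pr["mean"], scale=pr["sd"], random_state=rng))


def sample_participants(cspec: CohortSpec, seed: int) -> list[GenerativeParams]:
    """Draw per-participant generative parameters.

    Participant ``i`` uses the substream (seed, i), so adding participants
    leaves earlier ones unchanged.  Heterogeneity: one additive asymptote
    shift shared across constructions (sd ``lambda_sd``, asymptotes floored
    at 0), a shared multiplicative log-normal rate factor, and one additive
    intercept shift (floored at 0).
    """
    out = []
    for i in range(cspec.n_participants):
        rng = np.random.default_rng([seed, i])
        ability = _sample_ability(rng)
        lam_shift = rng.normal(0.0, cspec.lambda_sd) if cspec.lambda_sd else 0.0
        beta_factor = (
            float(np.exp(rng.normal(0.0, cspec.beta_log_sd))) if cspec.beta_log_sd else 1.0
        )
        delta_shift = rng.normal(0.0, cspec.delta_sd) if cspec.delta_sd else 0.0
        params = {
            cons: SATParams(
                lam=max(0.0, p.lam + lam_shift),
                beta=p.beta * beta_factor,
                delta=max(0.0, p.delta + delta_shift),
            )
            for cons, p in cspec.true_params.items()
        }
        out.append(
            GenerativeParams(
                params=params,
                criterion=cspec.criterion,
                ability=ability,
                ability_slope_lambda=cspec.ability_slope_lambda,
                switch_prob=cspec.switch_prob,
                control_lambda_fraction=cspec.control_lambda_fraction,
                decision_delay_sigma=cspec.decision_delay_sigma,
                trials_per_cell=cspec.trials_per_cell,
            )
        )
    return out


def simulate_cohort(
    cspec: CohortSpec | None = None,
    design: DesignSpec | None = None,
    seed: int = 0,
) -> dict:
    """Simulate a full cohort; returns ``{"trials", "participants"}``.

    ``trials`` is the long trial table (one row per trial, lag codes in
    ``lag_1..lag_n`` columns); ``participants`` records ability scores and
    each participant's true parameters.
    """
    cspec = cspec or CohortSpec()
    design = design or DesignSpec()
    items = build_design(design, seed)
    gps = sample_participants(cspec, seed)
    lag_cols = [f"lag_{k}" for k in range(1, design.n_tones + 1)]
    trial_rows = []
    part_rows = []
    for i, gp in enumerate(gps):
        pid = f"P{i + 1:02d}"
        plist = i % design.n_lists
        # successive sessions rotate through the experimental lists, as in
        # the four-session procedure (48 trials/cell = all four lists)
        per_session = design.instances_per_type_per_list
        n_sessions = int(np.ceil(cspec.trials_per_cell / per_session))
        pool = pd.concat(
            [
                items[items["list"] == (plist + s) % design.n_lists]
                for s in range(n_sessions)
            ],
            ignore_index=True,
        )
        plan = (
            pool.groupby("sentence_type", sort=False)
            .head(cspec.trials_per_cell)
            .reset_index(drop=True)
        )
        for j, item in enumerate(plan.itertuples(index=False)):
            rng = np.random.default_rng([seed, i, j])
            codes = simulate_trial_lags(gp, item._asdict(), design, rng)
            row = {
                "participant": pid,
                "list": plist,
                "trial": j,
                "item": item.item,
                "sentence_type": item.sentence_type,
                "construction": item.construction,
                "acceptable": item.acceptable,
                "control_anomaly": item.control_anomaly,
            }
            row.update(dict(zip(lag_cols, codes)))
            trial_rows.append(row)
        prow = {"participant": pid, "list": plist, "ability": gp.ability}
        for cons, p in gp.params.items():
            eff = gp.curve_params(cons)
            prow[f"lambda[{cons}]"] = eff.lam
            prow[f"beta[{cons}]"] = eff.beta
            prow[f"delta[{cons}]"] = eff.delta
        part_rows.append(prow)
    return {
        "trials": pd.DataFrame(trial_rows),
        "participants": pd.DataFrame(part_rows),
    }
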