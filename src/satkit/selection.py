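"""Hierarchical model comparison across participants and the averaged data.

A ladder of nested parameter-sharing models (null 1λ-1β-1δ upward) is
compared pairwise by the change in adjusted R².  Consistency across
participants — not a formal test — is the selection currency: an added
parameter is warranted when the averaged-data fit improves by more than a
small threshold *and* a majority of individually fitted participants
improve.  Among the models that survive, the fewest-parameter model is
preferred, with ties between equally sized speed parameterisations broken
toward the intercept (δ) rather than the rate (β) — the conservative
reading when the two are empirically indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ComparisonError, ConfigError
from .fitting import LadderFits
from .model import SATResults, parse_model_spec

__all__ = [
    "SelectionRule",
    "ConsistencyReport",
    "compare_nested",
    "consistency_report",
    "select_preferred",
]


def compare_nested(fit_small: SATResults, fit_large: SATResults) -> float:
    """Adjusted-R² gain of the larger over the smaller nested model."""
    unit_s = getattr(fit_small, "unit", None)
    unit_l = getattr(fit_large, "unit", None)
    if unit_s != unit_l:
        raise ComparisonError(
            f"fits are for different data units: {unit_s!r} vs {unit_l!r}"
        )
    if fit_small.spec.k >= fit_large.spec.k:
        raise ComparisonError(
            f"expected k(small) < k(large), got {fit_small.spec.k} >= {fit_large.spec.k}"
        )
    return fit_large.rsquared_adj - fit_small.rsquared_adj


@dataclass
class ConsistencyReport:
    """Per-participant adjusted-R² deltas for one nested model pair."""

    small: str
    large: str
    deltas: pd.Series  # indexed by participant
    avg_delta: float | None
    excluded: list = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(self.deltas.mean()) if len(self.deltas) else np.nan

    @property
    def min(self) -> float:
        return float(self.deltas.min()) if len(self.deltas) else np.nan

    @property
    def max(self) -> float:
        return float(self.deltas.max()) if len(self.deltas) else np.nan

    @property
    def n_improved(self) -> int:
        return int((self.deltas > 0).sum())

    @property
    def n(self) -> int:
        return int(len(self.deltas))

    def to_row(self) -> dict:
        return {
            "model_pair": f"{self.small} -> {self.large}",
            "mean_delta": self.mean,
            "min_delta": self.min,
            "max_delta": self.max,
            "n_improved": self.n_improved,
            "n": self.n,
            "avg_delta": self.avg_delta,
            "excluded": ";".join(map(str, self.excluded)),
        }

    def describe(self) -> str:
        return (
            f"{self.small} -> {self.large}: averaged-data dAdjR2 = "
            f"{self.avg_delta if self.avg_delta is not None else float('nan'):.4f}; "
            f"{self.n_improved}/{self.n} participants improved "
            f"(mean {self.mean:.4f}, min {self.min:.4f}, max {self.max:.4f})"
            + (f"; excluded: {', '.join(map(str, self.excluded))}" if self.excluded else "")
        )


def consistency_report(
    ladder: LadderFits,
    small: str,
    large: str,
    exclude_flagged: bool = True,
) -> ConsistencyReport:
    """Summarise the per-participant ΔadjR² for one nested pair.

    Participants whose fit for either model failed, or whose fit is flagged
    ``asymptote_overestimated`` (when ``exclude_flagged``), are listed as
    exclusions and omitted from the summaries — mirroring how participants
    that cannot be fit without overestimated asymptotes are reported.
    """
    deltas = {}
    excluded = []
    for unit in ladder.participants:
        fs = ladder.get(unit, small)
        fl = ladder.get(unit, large)
        if fs is None or fl is None:
            excluded.append(unit)
            continue
        if exclude_flagged and (
            fs.flags.get("asymptote_overestimated") or fl.flags.get("asymptote_overestimated")
        ):
            excluded.append(unit)
            continue
        deltas[unit] = compare_nested(fs, fl)
    avg_small = ladder.get("average", small)
    avg_large = ladder.get("average", large)
    avg_delta = (
        compare_nested(avg_small, avg_large)
        if avg_small is not None and avg_large is not None
        else None
    )
    return ConsistencyReport(
        small=small,
        large=large,
        deltas=pd.Series(deltas, dtype=float).sort_index(),
        avg_delta=avg_delta,
        excluded=sorted(excluded),
    )


@dataclass(frozen=True)
class SelectionRule:
    """Constants of the default preferred-model rule (all config-exposed)."""

    avg_threshold: float = 0.005
    majority: float = 0.5
    tie_break: str = "delta"  # prefer intercept over rate on k-ties


def select_preferred(
    reports: list[ConsistencyReport],
    rule: SelectionRule | None = None,
) -> str:
    """Pick the preferred model from pairwise consistency reports.

    An edge small->large is *accepted* iff the averaged-data ΔadjR² exceeds
    ``rule.avg_threshold`` and more than ``rule.majority`` of the
    non-excluded participants improve.  The candidate set is the closure of
    accepted edges from the smallest model; among candidates with no
    accepted outgoing edge the fewest-parameter model wins, ties going to
    the specification with more intercept (δ) groups.
    """
    if not reports:
        raise ConfigError("no consistency reports supplied")
    rule = rule or SelectionRule()
    models = {r.small for r in reports} | {r.large for r in reports}
    if len(models) == 1:
        return next(iter(models))
    accepted = {}
    for r in reports:
        ok = (
            r.avg_delta is not None
            and r.avg_delta > rule.avg_threshold
            and r.n > 0
            and r.n_improved > rule.majority * r.n
        )
        accepted[(r.small, r.large)] = ok
    root = min(models, key=lambda m: parse_model_spec(m).k)
    reachable = {root}
    changed = True
    while changed:
        changed = False
        for (s, l), ok in accepted.items():
            if ok and s in reachable and l not in reachable:
                reachable.add(l)
                changed = True
    survivors = [
        m
        for m in reachable
        if not any(ok and s == m for (s, l), ok in accepted.items())
    ]
    if not survivors:  # every reachable model had an accepted extension
        survivors = list(reachable)

    def sort_key(name: str):
        spec = parse_model_spec(name)
        delta_pref = -spec.n_delta if rule.tie_break == "delta" else -spec.n_beta
        return (spec.k, delta_pref, name)

    return sorted(survivors, key=sort_key)[0]
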