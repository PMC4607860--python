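"""Experimental design for the auditory MR-SAT paradigm.

The design crossed three sentence constructions — no material between the
subject noun and its verb (``NoInterp``), an interpolated object relative
clause (``OR``), and interpolated object + subject relative clauses
(``OR+SR``) — with acceptability.  Eight sentence types T1–T8 realise the
cross: each construction contributes one acceptable and one unacceptable
type, and the two longer constructions add a control type whose anomaly sits
inside the interpolated clause (used to verify that listeners process the
interpolated material, and excluded from d' scoring).

Items are rotated into experimental lists so that every list carries the
same number of instances of each type.  Responses are synchronised to a
train of tones presented every 350 ms starting 200 ms before the onset of
the sentence-final critical word, giving one response opportunity ("lag")
per tone across a 5000 ms response period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

#: canonical construction order used everywhere downstream
CONSTRUCTIONS = ("NoInterp", "OR", "OR+SR")

#: sentence type -> (construction, acceptable?, control_anomaly?)
TYPE_MAP = {
    "T1": ("NoInterp", True, False),
    "T2": ("NoInterp", False, False),
    "T3": ("OR", True, False),
    "T4": ("OR", False, False),
    "T5": ("OR", False, True),
    "T6": ("OR+SR", True, False),
    "T7": ("OR+SR", False, False),
    "T8": ("OR+SR", False, True),
}


@dataclass(frozen=True)
class DesignSpec:
    """Structural constants of one MR-SAT experiment.

    Defaults reproduce the published auditory subject–verb retrieval design:
    8 sentence types x 48 items rotated into 4 lists of 96 (12 instances of
    each type per list), with 15 response tones every 0.350 s beginning
    0.200 s before critical-word onset and a 5.000 s response period.
    """

    n_types: int = 8
    items_per_type: int = 48
    n_lists: int = 4
    sentences_per_list: int = 96
    instances_per_type_per_list: int = 12
    n_tones: int = 15
    tone_interval: float = 0.350
    tone_lead: float = 0.200
    response_period: float = 5.000
    type_map: dict = field(default_factory=lambda: dict(TYPE_MAP))

    def __post_init__(self):
        self.validate()

    @property
    def sentence_types(self) -> list[str]:
        return list(self.type_map)

    @property
    def constructions(self) -> list[str]:
        seen = []
        for cons, _, _ in self.type_map.values():
            if cons not in seen:
                seen.append(cons)
        return seen

    def validate(self) -> None:
        if len(self.type_map) != self.n_types:
            raise ConfigError(
                f"type_map has {len(self.type_map)} entries but n_types = {self.n_types}"
            )
        if self.n_types * self.items_per_type != self.n_lists * self.sentences_per_list:
            raise ConfigError(
                "violated: n_types * items_per_type = n_lists * sentences_per_list "
                f"({self.n_types}*{self.items_per_type} != {self.n_lists}*{self.sentences_per_list})"
            )
        if self.sentences_per_list != self.n_types * self.instances_per_type_per_list:
            raise ConfigError(
                "violated: sentences_per_list = n_types * instances_per_type_per_list "
                f"({self.sentences_per_list} != {self.n_types}*{self.instances_per_type_per_list})"
            )
        if self.n_tones > 0 and not self.tone_lead < self.tone_interval * self.n_tones:
            raise ConfigError(
                "violated: tone_lead < tone_interval * n_tones "
                f"({self.tone_lead} >= {self.tone_interval}*{self.n_tones})"
            )
        for kind, value in (("tone_interval", self.tone_interval),):
            if value <= 0:
                raise ConfigError(f"{kind} must be positive, got {value}")
        if self.tone_lead < 0 or self.response_period <= 0:
            raise ConfigError("tone_lead must be >= 0 and response_period > 0")


def lag_times(spec: DesignSpec) -> np.ndarray:
    """Tone (lag) times in seconds relative to critical-word onset.

    Lag ``k`` (1-based) occurs at ``-tone_lead + (k-1) * tone_interval``;
    the first tone leads the critical word, the rest pace the response
    period.
    """
    k = np.arange(spec.n_tones)
    return -spec.tone_lead + k * spec.tone_interval


def build_design(spec: DesignSpec, seed: int) -> pd.DataFrame:
    """Assign items to experimental lists.

    Every sentence type contributes ``items_per_type`` items; each list
    receives exactly ``instances_per_type_per_list`` of them, with the
    rotation chosen by a seeded shuffle so assignment is reproducible.

    Returns a DataFrame with columns ``item``, ``sentence_type``,
    ``construction``, ``acceptable``, ``control_anomaly``, ``list``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    rows = []
    item_counter = 0
    per_list = spec.items_per_type // spec.n_lists
    for stype in spec.sentence_types:
        cons, acc, ctrl = spec.type_map[stype]
        items = np.arange(item_counter, item_counter + spec.items_per_type)
        item_counter += spec.items_per_type
        order = rng.permutation(spec.items_per_type)
        for pos, item in enumerate(items[order]):
            rows.append(
                {
                    "item": int(item),
                    "sentence_type": stype,
                    "construction": cons,
                    "acceptable": acc,
                    "control_anomaly": ctrl,
                    "list": int(pos // per_list),
                }
            )
    df = pd.DataFrame(rows).sort_values(["list", "sentence_type", "item"], kind="stable")
    return df.reset_index(drop=True)
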