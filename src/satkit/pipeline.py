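"""End-to-end pipeline: simulate (or load) -> score -> fit -> compare -> stats.

A single YAML document configures every stage; one root seed drives all
randomness, with per-stage substreams derived by stable hashing of
(root seed, stage name).  Each run writes its artifacts plus a manifest
(config hash, seed, library versions) so that rerunning with the same
manifest reproduces the outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .design import DesignSpec
from .errors import ConfigError, SatkitError
from .fitting import FitConfig, fit_ladder
from .inference import mixed_anova, parameter_table
from .io import load_trials, save_trials, write_table
from .model import SATParams, parse_model_spec
from .scoring import cr_profile, dprime_curves, empirical_asymptote_table
from .selection import SelectionRule, consistency_report, select_preferred
from .simulate import CohortSpec, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

DEFAULT_MODELS = [
    "1λ-1β-1δ",
    "2λ-1β-1δ",
    "3λ-1β-1δ",
    "3λ-1β-2δ",
    "3λ-1β-3δ",
    "3λ-2β-1δ",
]

#: nested pairs compared by the selection stage (small, large)
DEFAULT_COMPARISONS = [
    ("1λ-1β-1δ", "2λ-1β-1δ"),
    ("2λ-1β-1δ", "3λ-1β-1δ"),
    ("3λ-1β-1δ", "3λ-1β-2δ"),
    ("3λ-1β-2δ", "3λ-1β-3δ"),
    ("3λ-1β-1δ", "3λ-2β-1δ"),
]


def stage_seed(root_seed: int, stage: str) -> int:
    """Per-stage substream seed, stable across runs and platforms (< 2^31)."""
    return (zlib.crc32(stage.encode()) ^ (root_seed & 0x7FFFFFFF)) & 0x7FFFFFFF


def _build_true_params(block: dict) -> dict:
    return {
        cons: SATParams(lam=v["lam"], beta=v["beta"], delta=v["delta"])
        for cons, v in block.items()
    }


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`."""

    design: DesignSpec = field(default_factory=DesignSpec)
    generative: CohortSpec | None = field(default_factory=CohortSpec)
    input_trials: str | None = None
    models: list = field(default_factory=lambda: list(DEFAULT_MODELS))
    comparisons: list = field(default_factory=lambda: list(DEFAULT_COMPARISONS))
    fit: FitConfig = field(default_factory=FitConfig)
    selection: SelectionRule = field(default_factory=SelectionRule)
    average_method: str = "pool"
    asymptote_m: int = 4
    fit_lags: list | None = None
    inference_quantities: list = field(
        default_factory=lambda: ["empirical_asymptote", "lambda", "beta", "delta"]
    )
    use_ability: bool = True
    seed: int = 0
    out_dir: str = "satkit_out"
    raw: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.generative is None and self.input_trials is None:
            raise ConfigError(
                "configuration needs either a 'generative' block or an input trials path"
            )
        for name in self.models:
            parse_model_spec(name)
        for small, large in self.comparisons:
            if small not in self.models or large not in self.models:
                raise ConfigError(f"comparison ({small}, {large}) not covered by models")
        if self.fit_lags is None:
            # drop the pre-onset tone by default: fit lags 2..n
            self.fit_lags = list(range(2, self.design.n_tones + 1))

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        cfg = dict(cfg or {})
        design = DesignSpec(**cfg.get("design", {}))
        gen_block = cfg.get("generative", None)
        generative = None
        if gen_block is not None:
            gen_block = dict(gen_block)
            if "true_params" in gen_block:
                gen_block["true_params"] = _build_true_params(gen_block["true_params"])
            generative = CohortSpec(**gen_block)
        fit_block = dict(cfg.get("fit", {}))
        if "algorithms" in fit_block:
            fit_block["algorithms"] = tuple(fit_block["algorithms"])
        if "bounds" in fit_block:
            fit_block["bounds"] = {k: tuple(v) for k, v in fit_block["bounds"].items()}
        scoring_block = cfg.get("scoring", {})
        sel_block = cfg.get("selection", {})
        inf_block = cfg.get("inference", {})
        return cls(
            design=design,
            generative=generative,
            input_trials=cfg.get("input", {}).get("trials"),
            models=list(cfg.get("models", DEFAULT_MODELS)),
            comparisons=[tuple(c) for c in cfg.get("comparisons", DEFAULT_COMPARISONS)],
            fit=FitConfig(**fit_block),
            selection=SelectionRule(**sel_block),
            average_method=scoring_block.get("average_method", "pool"),
            asymptote_m=scoring_block.get("asymptote_m", 4),
            fit_lags=scoring_block.get("fit_lags"),
            inference_quantities=list(
                inf_block.get(
                    "quantities", ["empirical_asymptote", "lambda", "beta", "delta"]
                )
            ),
            use_ability=bool(inf_block.get("ability", True)),
            seed=int(cfg.get("seed", 0)),
            out_dir=str(cfg.get("out_dir", "satkit_out")),
            raw=cfg,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def _manifest(cfg: PipelineConfig, seed: int) -> dict:
    import numpy, scipy, statsmodels  # noqa: F401  (versions only)

    return {
        "config_hash": cfg.config_hash(),
        "seed": seed,
        "versions": {
            "satkit": __version__,
            "python": sys.version.split()[0],
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }


def run_pipeline(cfg: PipelineConfig, out_dir=None, seed=None) -> dict:
    """Run every stage; returns a dict of in-memory artifacts.

    Any stage error aborts with the stage named; artifacts written by
    earlier stages are preserved on disk.
    """
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed if seed is None else seed
    artifacts: dict = {}
    stage = "simulate"
    try:
        if cfg.input_trials is not None:
            trials = load_trials(cfg.input_trials, cfg.design)
            participants = None
        else:
            sim = simulate_cohort(cfg.generative, cfg.design, stage_seed(seed, stage))
            trials = sim["trials"]
            participants = sim["participants"]
            write_table(participants, out / "participants.csv")
        save_trials(trials, out / "trials.csv")
        artifacts["trials"] = trials
        artifacts["participants"] = participants

        stage = "score"
        curves = dprime_curves(trials, cfg.design, average_method=cfg.average_method)
        write_table(curves, out / "curves.csv")
        profiles = cr_profile(trials, cfg.design)
        write_table(profiles, out / "cr_profiles.csv")
        asymptotes = empirical_asymptote_table(curves, m=cfg.asymptote_m)
        write_table(asymptotes, out / "empirical_asymptotes.csv")
        artifacts.update(curves=curves, cr_profiles=profiles, asymptotes=asymptotes)

        stage = "fit"
        specs = [parse_model_spec(name) for name in cfg.models]
        fit_cfg = dataclasses.replace(cfg.fit, seed=stage_seed(seed, stage))
        ladder = fit_ladder(curves, specs, fit_cfg, fit_lags=cfg.fit_lags)
        write_table(ladder.to_frame(), out / "fits.csv")
        artifacts["ladder"] = ladder

        stage = "compare"
        reports = [
            consistency_report(ladder, small, large) for small, large in cfg.comparisons
        ]
        report_rows = pd.DataFrame([r.to_row() for r in reports])
        write_table(report_rows, out / "consistency.csv")
        preferred = select_preferred(reports, cfg.selection)
        lines = ["# Model comparison", ""]
        lines += [r.describe() for r in reports]
        lines += ["", f"Preferred model: {preferred}"]
        (out / "selection.md").write_text("\n".join(lines) + "\n")
        artifacts.update(reports=reports, preferred=preferred)

        stage = "stats"
        abilities = None
        use_ability = cfg.use_ability and participants is not None
        if use_ability:
            abilities = participants.set_index("participant")["ability"]
        table = parameter_table(
            ladder,
            preferred,
            abilities=abilities,
            empirical=asymptotes,
        )
        write_table(table, out / "parameter_table.csv")
        fixed = ("construction", "ability", "interaction") if use_ability else ("construction",)
        effect_rows, contrast_rows = [], []
        for quantity in cfg.inference_quantities:
            if table[table["quantity"] == quantity].empty:
                continue
            res = mixed_anova(table, quantity, fixed=fixed)
            eff = res.effects.assign(quantity=quantity)
            con = res.contrasts.assign(quantity=quantity)
            effect_rows.append(eff)
            contrast_rows.append(con)
        effects = pd.concat(effect_rows, ignore_index=True) if effect_rows else pd.DataFrame()
        contrasts = (
            pd.concat(contrast_rows, ignore_index=True) if contrast_rows else pd.DataFrame()
        )
        write_table(effects, out / "stats_effects.csv")
        write_table(contrasts, out / "stats_contrasts.csv")
        artifacts.update(effects=effects, contrasts=contrasts, parameter_table=table)

        stage = "manifest"
        manifest = _manifest(cfg, seed)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        artifacts["manifest"] = manifest
    except SatkitError as exc:
        raise SatkitError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return artifacts
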