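"""File schemas and table I/O.

Two on-disk dialects describe trials:

* **lag codes** (canonical): one row per trial with design labels and
  ``lag_1..lag_n`` code columns — what the scoring stage consumes.
* **event streams**: one row per key event (participant, trial and design
  labels repeated, plus ``time_s``, ``key``, ``action``) — what MR-SAT
  response hardware typically exports.  Loading converts to lag codes via
  :func:`satkit.scoring.parse_stream`.

All tables are comma-separated with a header; floats are written at 6
significant digits so outputs diff cleanly across runs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .design import DesignSpec
from .errors import DataError
from .scoring import parse_stream
from .simulate import render_stream

__all__ = [
    "write_table",
    "load_trials",
    "save_trials",
    "save_event_streams",
    "load_curves",
]

FLOAT_FORMAT = "%.6g"

_META_COLS = [
    "participant",
    "list",
    "trial",
    "item",
    "sentence_type",
    "construction",
    "acceptable",
    "control_anomaly",
]


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def save_trials(trials: pd.DataFrame, path) -> Path:
    return write_table(trials, path)


def save_event_streams(trials: pd.DataFrame, spec: DesignSpec, path) -> Path:
    """Write the event-stream dialect equivalent of a lag-code trial table."""
    lag_cols = [f"lag_{k}" for k in range(1, spec.n_tones + 1)]
    frames = []
    for row in trials.itertuples(index=False):
        codes = [getattr(row, c) for c in lag_cols]
        ev = render_stream(codes, spec)
        for col in _META_COLS:
            ev[col] = getattr(row, col)
        frames.append(ev)
    events = pd.concat(frames, ignore_index=True)[_META_COLS + ["time_s", "key", "action"]]
    return write_table(events, path)


def _validate_lag_codes(df: pd.DataFrame, spec: DesignSpec, path) -> pd.DataFrame:
    lag_cols = [c for c in df.columns if c.startswith("lag_")]
    expected = [f"lag_{k}" for k in range(1, spec.n_tones + 1)]
    if lag_cols != expected:
        raise DataError(
            f"{path}: found {len(lag_cols)} lag columns, design specifies "
            f"{spec.n_tones} tones"
        )
    known = set(spec.type_map)
    bad = set(df["sentence_type"]) - known
    if bad:
        rows = df.index[df["sentence_type"].isin(bad)].tolist()
        raise DataError(
            f"{path}: unknown sentence type(s) {sorted(bad)} (first at data row "
            f"{rows[0] + 2})"
        )
    valid_codes = {"YES", "NO", "BOTH", "NONE"}
    for col in lag_cols:
        bad_codes = set(df[col].astype(str)) - valid_codes
        if bad_codes:
            raise DataError(f"{path}: invalid codes {sorted(bad_codes)} in {col}")
    for col in ("acceptable", "control_anomaly"):
        if df[col].dtype == object:
            df[col] = df[col].astype(str).str.lower().map({"true": True, "false": False})
        df[col] = df[col].astype(bool)
    return df


def load_trials(path, spec: DesignSpec | None = None, dialect: str | None = None) -> pd.DataFrame:
    """Load a trial file in either dialect; returns the lag-code form.

    The dialect is auto-detected from the header (``time_s`` -> event
    stream, ``lag_1`` -> lag codes) unless given explicitly.
    """
    spec = spec or DesignSpec()
    path = Path(path)
    if not path.exists():
        raise DataError(f"trial file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    if dialect is None:
        dialect = "events" if "time_s" in df.columns else "lag_codes"
    if dialect == "lag_codes":
        return _validate_lag_codes(df, spec, path)
    if dialect != "events":
        raise DataError(f"unknown trial dialect {dialect!r}")
    lag_cols = [f"lag_{k}" for k in range(1, spec.n_tones + 1)]
    rows = []
    for (participant, trial), grp in df.groupby(["participant", "trial"], sort=False):
        grp = grp.sort_values("time_s", kind="stable")
        codes = parse_stream(grp, spec, context=f"participant {participant}, trial {trial}")
        row = {c: grp.iloc[0][c] for c in _META_COLS}
        row.update(dict(zip(lag_cols, codes)))
        rows.append(row)
    out = pd.DataFrame(rows)
    return _validate_lag_codes(out, spec, path)


def load_curves(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"curve file not found: {path}")
    df = pd.read_csv(path)
    need = {"participant", "condition", "lag_time", "dprime"}
    missing = need - set(df.columns)
    if missing:
        raise DataError(f"{path}: curve table missing columns {sorted(missing)}")
    return df
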