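"""Keystroke event-table and trial-metadata I/O.

CSV dialects (UTF-8, comma-separated, mandatory header, fixed column order):

* events: ``pair_id,session,trial_id,player_role,phrase,position,pitch,onset_ms``
  with onsets in ms relative to trial onset, written at 0.001 ms precision;
* metadata: ``pair_id,session,trial_id,piece_id,familiarity,cue_melody,
  cue_bass,congruency,condition,instruction_type,participant`` (the derived
  columns are recomputed on read when absent).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import VALID_CUES
from .simulate import EVENT_COLUMNS, META_COLUMNS, derive_congruency, participant_label

TRIAL_KEY = ["pair_id", "session", "trial_id"]


class ValidationError(ValueError):
    """An event or metadata table violates the format contract."""


def derive_condition(meta_row) -> str:
    """Condition label FC/FI/UC/UI from familiarity and the two cues."""
    fam = meta_row["familiarity"]
    if fam not in ("F", "U"):
        raise ValidationError(f"familiarity must be 'F' or 'U', got {fam!r}")
    return fam + derive_congruency(meta_row["cue_melody"], meta_row["cue_bass"])


def complete_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Fill in the derived metadata columns (congruency, condition, ...)."""
    meta = meta.copy()
    bad = ~meta["cue_melody"].isin(VALID_CUES) | ~meta["cue_bass"].isin(VALID_CUES)
    if bad.any():
        row = meta[bad].iloc[0]
        raise ValidationError(
            f"unknown cue label in trial {tuple(row[TRIAL_KEY])}: "
            f"({row['cue_melody']!r}, {row['cue_bass']!r}); expected one of {VALID_CUES}"
        )
    meta["congruency"] = np.where(meta["cue_melody"] == meta["cue_bass"], "C", "I")
    meta["condition"] = meta["familiarity"] + meta["congruency"]
    code = {"up": "U", "down": "D"}
    meta["instruction_type"] = meta["cue_melody"].map(code) + meta["cue_bass"].map(code)
    if "participant" not in meta.columns:
        meta["participant"] = [
            participant_label(p, s) for p, s in zip(meta["pair_id"], meta["session"])
        ]
    return meta


def validate_events(events: pd.DataFrame) -> None:
    """Enforce the event-table invariants; raise ValidationError naming the
    first offending trial."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValidationError(f"missing event columns: {missing}")
    if not events["player_role"].isin(["melody", "bass"]).all():
        bad = events.loc[~events["player_role"].isin(["melody", "bass"]), "player_role"].iloc[0]
        raise ValidationError(f"unknown player_role {bad!r}")
    if not events["phrase"].isin([1, 2]).all():
        raise ValidationError("phrase must be 1 or 2")
    if ((events["position"] < 1) | (events["position"] > 7)).any():
        raise ValidationError("position must be in 1..7 within a phrase")
    if ((events["pitch"] < 0) | (events["pitch"] > 127)).any():
        raise ValidationError("pitch must be a MIDI note number 0-127")
    if (events["onset_ms"] < 0).any():
        trial = events.loc[events["onset_ms"] < 0].iloc[0]
        raise ValidationError(f"negative onset in trial {tuple(trial[TRIAL_KEY])}")

    keys = TRIAL_KEY + ["player_role", "phrase", "position"]
    dup = events.duplicated(keys)
    if dup.any():
        row = events[dup].iloc[0]
        raise ValidationError(
            f"duplicate position in trial {tuple(row[TRIAL_KEY])}: "
            f"({row['player_role']}, phrase {row['phrase']}, position {row['position']})"
        )

    g = events.sort_values(keys).groupby(TRIAL_KEY + ["player_role", "phrase"], sort=False)
    non_mono = g["onset_ms"].apply(lambda s: bool((np.diff(s.to_numpy()) <= 0).any()))
    if non_mono.any():
        key = non_mono[non_mono].index[0]
        raise ValidationError(f"non-monotone onsets in trial {key[:3]} ({key[3]}, phrase {key[4]})")

    roles = events.groupby(TRIAL_KEY)["player_role"].agg(lambda s: frozenset(s))
    incomplete = roles[roles != frozenset({"melody", "bass"})]
    if len(incomplete):
        raise ValidationError(
            f"trial {incomplete.index[0]} lacks one player's events (dyadic completeness)"
        )


_EVENT_DTYPES = {
    "pair_id": np.int64,
    "session": np.int64,
    "trial_id": np.int64,
    "phrase": np.int64,
    "position": np.int64,
    "pitch": np.int64,
    "onset_ms": np.float64,
}


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write the events CSV dialect (onsets rounded to 0.001 ms)."""
    out = events[EVENT_COLUMNS].copy()
    out["onset_ms"] = out["onset_ms"].round(3)
    out.to_csv(path, index=False, float_format="%.3f")


def read_events(path: str | Path, validate: bool = True) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    events = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValidationError(f"{path}: missing event columns: {missing}")
    events = events[EVENT_COLUMNS].astype(_EVENT_DTYPES)
    if validate:
        validate_events(events)
    return events


def write_meta(meta: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in META_COLUMNS if c in meta.columns]
    extra = [c for c in meta.columns if c.startswith("inj_") or c == "technical_error"]
    meta[cols + extra].to_csv(path, index=False)


def read_meta(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = pd.read_csv(path)
    required = ["pair_id", "session", "trial_id", "piece_id", "familiarity", "cue_melody", "cue_bass"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValidationError(f"{path}: missing metadata columns: {missing}")
    return complete_meta(meta)
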