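"""Trial quality control: wrong notes, wrong tempo, outlier intervals.

The exclusion pipeline runs in a fixed order and each later stage sees only
the survivors of the earlier ones:

1. any wrong key by either player excludes the trial;
2. the six second-phrase IKIs of each player are classified to the nearest
   constant-tempo template by mean squared error (fast 400 ms, slow 625 ms,
   no-change 500 ms); a trial is excluded when either player's best-fitting
   tempo differs from that player's instruction (exact MSE ties that include
   the instructed tempo keep the trial);
3. optional technical-error flags from the metadata are honoured;
4. trials containing a first-phrase IKI outside the pooled 1st-99th
   percentile band (both players, all conditions pooled) are eliminated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CUE_TEMPO, DesignSpec, ScoreSpec, tempo_templates
from .io_events import TRIAL_KEY
from .metrics import iki_wide

MIN_POOLED_IKIS = 100


class QCError(ValueError):
    pass


@dataclass
class QCReport:
    """Per-trial flags plus the derived retention bookkeeping."""

    flags: pd.DataFrame  # indexed by trial key; boolean flag columns + 'retained'
    iki_bounds: tuple[float, float] | None  # pooled [p1, p99] in ms, None if skipped
    retained_by_condition: pd.Series  # condition -> retained trial count

    @property
    def n_total(self) -> int:
        return len(self.flags)

    @property
    def n_retained(self) -> int:
        return int(self.flags["retained"].sum())

    def mean_retained_per_pair(self) -> pd.Series:
        """Mean retained trials per pair for each condition (the layout used
        to report final trial numbers: FC, FI, UC, UI)."""
        f = self.flags.reset_index()
        per_pair = f[f["retained"]].groupby(["condition", "pair_id"]).size()
        n_pairs = f["pair_id"].nunique()
        return per_pair.groupby("condition").sum() / n_pairs

    def reasons(self) -> pd.Series:
        flag_cols = [c for c in self.flags.columns if c not in ("retained", "condition")]
        def reason(row):
            hit = [c for c in flag_cols if row[c]]
            return "+".join(hit) if hit else ""
        return self.flags.apply(reason, axis=1)


def flag_wrong_notes(events: pd.DataFrame, meta: pd.DataFrame, scores: list[ScoreSpec]) -> pd.Series:
    """True for trials where any played pitch deviates from the score."""
    bank = {s.piece_id: s for s in scores}
    missing = set(meta["piece_id"]) - set(bank)
    if missing:
        raise QCError(f"no score for piece(s): {sorted(missing)}")
    ev = events.merge(meta[TRIAL_KEY + ["piece_id"]], on=TRIAL_KEY, how="left")
    idx = (ev["phrase"].to_numpy() - 1) * 7 + ev["position"].to_numpy() - 1
    expected = np.array(
        [
            bank[piece].pitches(role)[i]
            for piece, role, i in zip(ev["piece_id"], ev["player_role"], idx)
        ]
    )
    ev["wrong"] = ev["pitch"].to_numpy() != expected
    flags = ev.groupby(TRIAL_KEY)["wrong"].any()
    return flags.reindex(pd.MultiIndex.from_frame(meta[TRIAL_KEY]), fill_value=False)


def classify_tempo(ikis_phase2, design: DesignSpec | None = None) -> str:
    """Best-fitting tempo label for six second-phrase IKIs (min MSE).

    Raises on a wrong interval count; on an exact tie the lexicographically
    fixed template order (fast, slow, none) decides, but callers that know
    the instructed tempo should use :func:`tempo_matches_instruction`, which
    resolves ties in favour of the instruction.
    """
    labels = tied_tempo_labels(ikis_phase2, design)
    return labels[0]


def tied_tempo_labels(ikis_phase2, design: DesignSpec | None = None) -> list[str]:
    """All templates attaining the minimal MSE, in (fast, slow, none) order."""
    design = design or DesignSpec()
    ikis = np.asarray(ikis_phase2, dtype=float)
    if ikis.shape != (6,):
        raise QCError(f"expected exactly 6 second-phrase IKIs, got shape {ikis.shape}")
    if (ikis <= 0).any():
        raise QCError("IKIs must be positive")
    templates = tempo_templates(design)
    mse = {label: float(np.mean((ikis - t) ** 2)) for label, t in templates.items()}
    best = min(mse.values())
    return [label for label in ("fast", "slow", "none") if mse[label] == best]


def tempo_matches_instruction(ikis_phase2, instructed: str, design: DesignSpec | None = None) -> bool:
    """True when the instructed tempo is among the minimal-MSE templates.

    Only a *demonstrably better-fitting* wrong tempo excludes a trial; exact
    ties that include the instruction keep it.
    """
    if instructed not in ("fast", "slow", "none"):
        raise QCError(f"unknown instructed tempo {instructed!r}")
    return instructed in tied_tempo_labels(ikis_phase2, design)


def flag_mistempo(events: pd.DataFrame, meta: pd.DataFrame, design: DesignSpec | None = None) -> pd.DataFrame:
    """Per-trial mistempo flags for each player (phrase-2 template check)."""
    design = design or DesignSpec()
    ikis = iki_wide(events, phrase=2)  # (trial key) x player -> 6 intervals
    instructed = {
        "melody": meta.set_index(TRIAL_KEY)["cue_melody"].map(CUE_TEMPO),
        "bass": meta.set_index(TRIAL_KEY)["cue_bass"].map(CUE_TEMPO),
    }
    out = pd.DataFrame(
        {"mistempo_melody": False, "mistempo_bass": False},
        index=pd.MultiIndex.from_frame(meta[TRIAL_KEY]),
    )
    for role in ("melody", "bass"):
        col = f"mistempo_{role}"
        for key, vec in ikis[role].items():
            out.loc[key, col] = not tempo_matches_instruction(vec, instructed[role].loc[key], design)
    return out


def trim_iki_outliers(
    events: pd.DataFrame,
    lower_pct: float = 1.0,
    upper_pct: float = 99.0,
) -> tuple[pd.Series, tuple[float, float] | None]:
    """Flag trials containing a phrase-1 IKI strictly outside the pooled
    [lower_pct, upper_pct] percentile band (linear-interpolation percentiles,
    both players and all trials pooled).

    Returns (flags indexed by trial key, (lo, hi) bounds).  With fewer than
    100 pooled IKIs the filter is skipped with a warning (bounds None).
    """
    ikis = iki_wide(events, phrase=1)
    keys = sorted({k for role in ikis.values() for k in role})
    index = pd.MultiIndex.from_tuples(keys, names=TRIAL_KEY)
    pool = np.concatenate([vec for role in ikis.values() for vec in role.values()]) if keys else np.array([])
    if pool.size < MIN_POOLED_IKIS:
        warnings.warn(
            f"only {pool.size} pooled phrase-1 IKIs (< {MIN_POOLED_IKIS}); outlier filter skipped",
            stacklevel=2,
        )
        return pd.Series(False, index=index, name="iki_outlier"), None
    lo, hi = np.percentile(pool, [lower_pct, upper_pct], method="linear")
    flags = pd.Series(False, index=index, name="iki_outlier")
    for role in ("melody", "bass"):
        for key, vec in ikis[role].items():
            if ((vec < lo) | (vec > hi)).any():
                flags.loc[key] = True
    return flags, (float(lo), float(hi))


def run_qc(
    events: pd.DataFrame,
    meta: pd.DataFrame,
    scores: list[ScoreSpec] | None = None,
    design: DesignSpec | None = None,
    iki_bounds: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Full exclusion pipeline; returns (retained events, report).

    ``iki_bounds`` freezes the percentile band (used to show idempotence);
    by default the band is computed from the survivors of the earlier
    stages.
    """
    design = design or DesignSpec()
    scores = list(scores) if scores is not None else list(design.pieces)
    key_index = pd.MultiIndex.from_frame(meta[TRIAL_KEY])
    flags = pd.DataFrame(index=key_index)
    flags["wrong_note"] = flag_wrong_notes(events, meta, scores)
    flags = flags.join(flag_mistempo(events, meta, design))
    flags["technical_error"] = (
        meta.set_index(TRIAL_KEY)["technical_error"].astype(bool)
        if "technical_error" in meta.columns
        else False
    )

    pre = ~(
        flags["wrong_note"]
        | flags["mistempo_melody"]
        | flags["mistempo_bass"]
        | flags["technical_error"]
    )
    surviving = events.set_index(TRIAL_KEY).loc[key_index[pre]].reset_index()
    if iki_bounds is None:
        out_flags, bounds = trim_iki_outliers(surviving)
    else:
        bounds = iki_bounds
        ikis = iki_wide(surviving, phrase=1)
        out_flags = pd.Series(False, index=key_index)
        lo, hi = bounds
        for role in ("melody", "bass"):
            for key, vec in ikis[role].items():
                if ((vec < lo) | (vec > hi)).any():
                    out_flags.loc[key] = True
    flags["iki_outlier"] = out_flags.reindex(key_index, fill_value=False)
    flags["retained"] = pre & ~flags["iki_outlier"]

    flags["condition"] = meta.set_index(TRIAL_KEY)["condition"]
    retained_events = events.set_index(TRIAL_KEY).loc[key_index[flags["retained"]]].reset_index()
    report = QCReport(
        flags=flags,
        iki_bounds=bounds,
        retained_by_condition=flags[flags["retained"]].groupby("condition").size(),
    )
    return retained_events, report
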