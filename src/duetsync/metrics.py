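"""Synchronization accuracy, stability, and adaptation metrics.

All metrics are computed on first-phrase keystrokes of retained trials:

* signed asynchrony a(n) = melody onset - bass onset at position n (positive
  = scanner pianist late), mean-centered per keystroke position and piece
  within each participant-session;
* accuracy: per participant and tempo-instruction type, the mean signed
  asynchrony across keystrokes 1-7 of all trials; absolute values of these
  means are then averaged into the congruent/incongruent condition value;
* stability: per-trial SD of the signed asynchronies (n-1 denominator),
  averaged across trials per condition;
* adaptation: lagged cross-correlations of the two players' six IKIs with
  the scanner (melody) pianist as reference -- lag -1 pairs melody IKI n
  with bass IKI n-1 (how much the scanner pianist adapts to the partner),
  lag +1 pairs melody IKI n with bass IKI n+1 (partner adapting to the
  scanner pianist).  Coefficients are Fisher z-transformed before averaging.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

TRIAL_KEY = ["pair_id", "session", "trial_id"]
LAGS = (-1, 0, 1)
LAG_COLS = {-1: "lag_m1", 0: "lag_0", 1: "lag_p1"}
_R_CLIP = 1.0 - 1e-12


def onsets_wide(events: pd.DataFrame, phrase: int = 1, n_positions: int = 7) -> pd.DataFrame:
    """Pivot one phrase to a (trial x (player, position)) onset table.

    Trials missing any of the 2 x ``n_positions`` onsets are dropped with a
    warning.
    """
    sub = events[events["phrase"] == phrase]
    wide = sub.pivot_table(
        index=TRIAL_KEY, columns=["player_role", "position"], values="onset_ms", aggfunc="first"
    )
    full_cols = pd.MultiIndex.from_product(
        [["melody", "bass"], range(1, n_positions + 1)], names=["player_role", "position"]
    )
    wide = wide.reindex(columns=full_cols)
    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"{int(incomplete.sum())} trial(s) skipped: missing phrase-{phrase} positions",
            stacklevel=2,
        )
        wide = wide[~incomplete]
    return wide


def iki_wide(events: pd.DataFrame, phrase: int = 1) -> dict[str, dict[tuple, np.ndarray]]:
    """Per-trial inter-keystroke-interval vectors (6 per player) for one phrase."""
    wide = onsets_wide(events, phrase=phrase)
    out: dict[str, dict[tuple, np.ndarray]] = {}
    for role in ("melody", "bass"):
        mat = wide[role].to_numpy()
        ikis = np.diff(mat, axis=1)
        out[role] = {key: ikis[i] for i, key in enumerate(wide.index)}
    return out


def compute_asynchronies(events: pd.DataFrame, phrase: int = 1) -> pd.DataFrame:
    """Signed asynchrony series per trial, long format.

    Columns: trial key, position, asynchrony (melody onset - bass onset, ms;
    positive means the melody/scanner pianist struck later).
    """
    wide = onsets_wide(events, phrase=phrase)
    asyn = wide["melody"].to_numpy() - wide["bass"].to_numpy()
    n_pos = asyn.shape[1]
    out = pd.DataFrame(
        {
            "pair_id": np.repeat(wide.index.get_level_values("pair_id"), n_pos),
            "session": np.repeat(wide.index.get_level_values("session"), n_pos),
            "trial_id": np.repeat(wide.index.get_level_values("trial_id"), n_pos),
            "position": np.tile(np.arange(1, n_pos + 1), len(wide)),
            "asynchrony": asyn.reshape(-1),
        }
    )
    return out


def mean_center(
    asynchronies: pd.DataFrame,
    meta: pd.DataFrame,
    scope: tuple[str, ...] = ("pair_id", "session"),
) -> pd.DataFrame:
    """Mean-center asynchronies per keystroke position and piece.

    The centering cell is scope x piece x position pooled over all retained
    trials (all instruction types); the default scope is the participant-
    session, so piece/position difficulty is removed without mixing dyads.
    Adds ``asynchrony_centered`` and a ``single_trial_cell`` flag (cells with
    one trial center to exactly 0).
    """
    df = asynchronies.merge(meta[TRIAL_KEY + ["piece_id"]], on=TRIAL_KEY, how="left")
    cell = list(scope) + ["piece_id", "position"]
    grp = df.groupby(cell)["asynchrony"]
    df["asynchrony_centered"] = df["asynchrony"] - grp.transform("mean")
    df["single_trial_cell"] = grp.transform("size") == 1
    return df


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise sample Pearson r; rows with zero variance give NaN."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=1) / (sx * sy)
    r[(sx == 0) | (sy == 0)] = np.nan
    return r


def fisher_z(r) -> np.ndarray | float:
    """atanh with |r| clipped just inside 1 (so r = +/-1 stays finite)."""
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def lag_crosscorr(iki_melody, iki_bass, lag: int) -> tuple[float, float]:
    """(r, Fisher z) of the two IKI vectors at one lag.

    Reference is the melody (scanner) pianist: lag -1 correlates melody IKI
    n with bass IKI n-1 (5 pairs), lag +1 melody IKI n with bass IKI n+1
    (5 pairs), lag 0 uses all 6 aligned pairs.  Zero variance in either
    member yields (nan, nan).
    """
    x = np.asarray(iki_melody, dtype=float)
    y = np.asarray(iki_bass, dtype=float)
    if x.shape != (6,) or y.shape != (6,):
        raise ValueError(f"expected two length-6 IKI vectors, got {x.shape} and {y.shape}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("IKI vectors must be finite")
    if lag == 0:
        xs, ys = x, y
    elif lag == -1:
        xs, ys = x[1:], y[:-1]
    elif lag == 1:
        xs, ys = x[:-1], y[1:]
    else:
        raise ValueError(f"lag must be -1, 0, or +1, got {lag}")
    r = float(_pearson_rows(xs[None, :], ys[None, :])[0])
    z = float(fisher_z(r)) if np.isfinite(r) else float("nan")
    return r, z


def trial_lag_correlations(events: pd.DataFrame, phrase: int = 1) -> pd.DataFrame:
    """Per-trial r and Fisher z at lags -1, 0, +1 (vectorized over trials)."""
    wide = onsets_wide(events, phrase=phrase)
    iki_m = np.diff(wide["melody"].to_numpy(), axis=1)
    iki_b = np.diff(wide["bass"].to_numpy(), axis=1)
    out = pd.DataFrame(index=wide.index).reset_index()
    for lag in LAGS:
        if lag == 0:
            r = _pearson_rows(iki_m, iki_b)
        elif lag == -1:
            r = _pearson_rows(iki_m[:, 1:], iki_b[:, :-1])
        else:
            r = _pearson_rows(iki_m[:, :-1], iki_b[:, 1:])
        col = LAG_COLS[lag]
        out[f"r_{col}"] = r
        out[f"z_{col}"] = np.where(np.isfinite(r), fisher_z(r), np.nan)
    return out


def trial_metrics(events: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-trial summary: mean and SD of centered asynchronies + lag r/z."""
    centered = mean_center(compute_asynchronies(events), meta)
    per_trial = centered.groupby(TRIAL_KEY).agg(
        mean_async=("asynchrony_centered", "mean"),
        sd_async=("asynchrony_centered", lambda s: s.std(ddof=1)),
    )
    lags = trial_lag_correlations(events).set_index(TRIAL_KEY)
    return per_trial.join(lags).reset_index()


def accuracy_summary(
    centered: pd.DataFrame,
    meta: pd.DataFrame,
    pool: str = "keystrokes",
    per_trial_abs: bool = False,
) -> pd.DataFrame:
    """Mean absolute asynchrony per participant x condition.

    Default reading: per participant and tempo-instruction type (UU, DD, UD,
    DU) the signed asynchronies of keystrokes 1-7 of all retained trials are
    averaged; absolute values of these four means are then averaged into the
    condition value (C <- {UU, DD}, I <- {UD, DU}) separately per
    familiarity.  ``pool='trials'`` averages per-trial means first (identical
    for balanced counts); ``per_trial_abs=True`` is the sensitivity variant
    that takes absolute values per trial before any averaging.
    """
    if pool not in ("keystrokes", "trials"):
        raise ValueError(f"pool must be 'keystrokes' or 'trials', got {pool!r}")
    df = centered.merge(
        meta[TRIAL_KEY + ["participant", "familiarity", "congruency", "condition", "instruction_type"]],
        on=TRIAL_KEY,
        how="left",
    )
    if per_trial_abs:
        per_trial = df.groupby(TRIAL_KEY + ["participant", "condition"], as_index=False)[
            "asynchrony_centered"
        ].mean()
        per_trial["value"] = per_trial["asynchrony_centered"].abs()
        out = per_trial.groupby(["participant", "condition"], as_index=False)["value"].mean()
        return out.rename(columns={"value": "mean_abs_async"})
    keys = ["participant", "familiarity", "congruency", "instruction_type"]
    if pool == "keystrokes":
        instr = df.groupby(keys)["asynchrony_centered"].mean()
    else:
        per_trial = df.groupby(TRIAL_KEY + keys)["asynchrony_centered"].mean()
        instr = per_trial.groupby(keys).mean()
    instr = instr.abs().reset_index(name="abs_instr_mean")
    instr["condition"] = instr["familiarity"] + instr["congruency"]
    out = instr.groupby(["participant", "condition"], as_index=False)["abs_instr_mean"].mean()
    return out.rename(columns={"abs_instr_mean": "mean_abs_async"})


def stability_summary(centered: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Mean per-trial SD of signed asynchronies per participant x condition."""
    per_trial = centered.groupby(TRIAL_KEY)["asynchrony_centered"].std(ddof=1).rename("sd")
    df = per_trial.reset_index().merge(
        meta[TRIAL_KEY + ["participant", "condition"]], on=TRIAL_KEY, how="left"
    )
    return df.groupby(["participant", "condition"], as_index=False)["sd"].mean().rename(
        columns={"sd": "mean_sd_async"}
    )


def adaptation_summary(trial_lags: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Mean Fisher z per participant x condition x lag (NaN trials dropped)."""
    df = trial_lags.merge(meta[TRIAL_KEY + ["participant", "condition"]], on=TRIAL_KEY, how="left")
    z_cols = [f"z_{LAG_COLS[lag]}" for lag in LAGS]
    return df.groupby(["participant", "condition"], as_index=False)[z_cols].mean()


def condition_summary(
    events: pd.DataFrame,
    meta: pd.DataFrame,
    pool: str = "keystrokes",
    per_trial_abs: bool = False,
) -> pd.DataFrame:
    """Full per-participant-per-condition summary table.

    One row per participant x condition with mean_abs_async (ms),
    mean_sd_async (ms), and mean Fisher z at lags -1, 0, +1.
    """
    centered = mean_center(compute_asynchronies(events), meta)
    acc = accuracy_summary(centered, meta, pool=pool, per_trial_abs=per_trial_abs)
    stab = stability_summary(centered, meta)
    adapt = adaptation_summary(trial_lag_correlations(events), meta)
    out = acc.merge(stab, on=["participant", "condition"], how="outer").merge(
        adapt, on=["participant", "condition"], how="outer"
    )
    return out.sort_values(["participant", "condition"]).reset_index(drop=True)
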