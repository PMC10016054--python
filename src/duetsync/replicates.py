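"""Vectorized replicate engine for calibration studies (type I error, power).

Runs the simulate -> asynchrony -> centering -> condition-summary chain as
pure array operations so that hundreds of replicate datasets can be scored
in seconds.  It shares the onset kernel (:func:`duetsync.simulate.
onsets_from_noise`) and implements exactly the same summary definitions as
:mod:`duetsync.metrics`; the two paths are cross-checked for numerical
equality in the test suite.  Noise for each replicate comes from a single
seeded stream (the per-trial substream bookkeeping of ``simulate_dataset``
is unnecessary here because replicates are scored, not persisted).

Intended for injection-free parameter studies: QC is a no-op when the
injection probabilities are zero, so it is skipped.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .design import CONDITIONS, DesignSpec, DyadParams, INSTRUCTION_TYPES
from .simulate import draw_noise, make_trial_meta, onsets_from_noise

Z_CLIP = 1.0 - 1e-12


class _MetaCodes:
    """Integer-coded trial design shared by every replicate."""

    def __init__(self, design: DesignSpec):
        meta = make_trial_meta(design)
        self.meta = meta
        self.participants = sorted(meta["participant"].unique())
        self.n_participants = len(self.participants)
        part_code = {p: i for i, p in enumerate(self.participants)}
        self.part = meta["participant"].map(part_code).to_numpy()
        pieces = sorted(meta["piece_id"].unique())
        self.n_pieces = len(pieces)
        self.piece = meta["piece_id"].map({p: i for i, p in enumerate(pieces)}).to_numpy()
        self.cond = meta["condition"].map({c: i for i, c in enumerate(CONDITIONS)}).to_numpy()
        self.fam = (meta["familiarity"] == "U").to_numpy().astype(np.int64)  # 0=F, 1=U
        self.instr = meta["instruction_type"].map(
            {t: i for i, t in enumerate(INSTRUCTION_TYPES)}
        ).to_numpy()


def _group_mean(values: np.ndarray, group: np.ndarray, n_groups: int) -> tuple[np.ndarray, np.ndarray]:
    sums = np.bincount(group, weights=values, minlength=n_groups)
    counts = np.bincount(group, minlength=n_groups)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    return means, counts


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=1) / (sx * sy)
    r[(sx == 0) | (sy == 0)] = np.nan
    return r


def summaries_from_onsets(onsets: np.ndarray, codes: _MetaCodes) -> dict[str, np.ndarray]:
    """Condition summaries from a (trials, 2, 14) onset array.

    Returns ``mean_abs_async`` and ``mean_sd_async`` as (participants, 4)
    arrays (condition order FC, FI, UC, UI) and ``z`` as (participants, 4,
    3) for lags (-1, 0, +1).
    """
    npp = onsets.shape[2] // 2
    asyn = onsets[:, 0, :npp] - onsets[:, 1, :npp]  # melody - bass, phrase 1
    n_trials = asyn.shape[0]
    n_part = codes.n_participants

    # --- mean-centering per participant-session x piece x position ---
    cell = codes.part * codes.n_pieces + codes.piece
    n_cells = n_part * codes.n_pieces
    centered = np.empty_like(asyn)
    for pos in range(npp):
        means, _ = _group_mean(asyn[:, pos], cell, n_cells)
        centered[:, pos] = asyn[:, pos] - means[cell]

    # --- accuracy: abs of pooled signed mean per (participant, fam, instruction) ---
    g = (codes.part * 2 + codes.fam) * 4 + codes.instr
    n_g = n_part * 8
    g_rows = np.repeat(g, npp)
    sums = np.bincount(g_rows, weights=centered.reshape(-1), minlength=n_g)
    counts = np.bincount(g_rows, minlength=n_g)
    with np.errstate(invalid="ignore"):
        instr_mean = np.abs(sums / counts).reshape(n_part, 2, 4)
    # condition order FC, FI, UC, UI; C <- {UU, DD} (instr 0, 1), I <- {UD, DU} (2, 3)
    mean_abs = np.empty((n_part, 4))
    mean_abs[:, 0] = instr_mean[:, 0, :2].mean(axis=1)  # FC
    mean_abs[:, 1] = instr_mean[:, 0, 2:].mean(axis=1)  # FI
    mean_abs[:, 2] = instr_mean[:, 1, :2].mean(axis=1)  # UC
    mean_abs[:, 3] = instr_mean[:, 1, 2:].mean(axis=1)  # UI

    # --- stability: per-trial SD (ddof=1) then mean per participant x condition ---
    sd = centered.std(axis=1, ddof=1)
    pc = codes.part * 4 + codes.cond
    sd_mean, _ = _group_mean(sd, pc, n_part * 4)
    mean_sd = sd_mean.reshape(n_part, 4)

    # --- adaptation: lagged cross-correlations, Fisher z, condition means ---
    iki_m = np.diff(onsets[:, 0, :npp], axis=1)
    iki_b = np.diff(onsets[:, 1, :npp], axis=1)
    z = np.empty((n_part, 4, 3))
    for li, lag in enumerate((-1, 0, 1)):
        if lag == 0:
            r = _pearson_rows(iki_m, iki_b)
        elif lag == -1:
            r = _pearson_rows(iki_m[:, 1:], iki_b[:, :-1])
        else:
            r = _pearson_rows(iki_m[:, :-1], iki_b[:, 1:])
        zt = np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP))
        ok = np.isfinite(zt)
        sums = np.bincount(pc[ok], weights=zt[ok], minlength=n_part * 4)
        counts = np.bincount(pc[ok], minlength=n_part * 4)
        with np.errstate(invalid="ignore"):
            z[:, :, li] = (sums / counts).reshape(n_part, 4)
    return {"mean_abs_async": mean_abs, "mean_sd_async": mean_sd, "z": z}


def simulate_summaries(
    params: DyadParams,
    design: DesignSpec,
    n_replicates: int,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Condition summaries for ``n_replicates`` independent datasets.

    Returns arrays with a leading replicate axis: ``mean_abs_async`` and
    ``mean_sd_async`` of shape (reps, participants, 4) and ``z`` of shape
    (reps, participants, 4, 3).  Injection probabilities are forced to zero
    (replicate studies score clean trials; QC is the identity there).
    """
    params = replace(params, p_wrong_note=0.0, p_mistempo=0.0, p_outlier=0.0)
    codes = _MetaCodes(design)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    out = {
        "mean_abs_async": np.empty((n_replicates, codes.n_participants, 4)),
        "mean_sd_async": np.empty((n_replicates, codes.n_participants, 4)),
        "z": np.empty((n_replicates, codes.n_participants, 4, 3)),
    }
    for rep in range(n_replicates):
        noise = draw_noise(rng, len(codes.meta))
        onsets, _ = onsets_from_noise(params, design, codes.meta, noise)
        s = summaries_from_onsets(onsets, codes)
        for key in out:
            out[key][rep] = s[key]
    out["participants"] = np.array(codes.participants)
    return out


def summary_frame(summary: dict[str, np.ndarray], participants) -> pd.DataFrame:
    """Convert one replicate's summary arrays to the ConditionSummary layout
    of :func:`duetsync.metrics.condition_summary` (for cross-checking)."""
    rows = []
    for i, part in enumerate(participants):
        for j, cond in enumerate(CONDITIONS):
            rows.append(
                {
                    "participant": part,
                    "condition": cond,
                    "mean_abs_async": summary["mean_abs_async"][i, j],
                    "mean_sd_async": summary["mean_sd_async"][i, j],
                    "z_lag_m1": summary["z"][i, j, 0],
                    "z_lag_0": summary["z"][i, j, 1],
                    "z_lag_p1": summary["z"][i, j, 2],
                }
            )
    return pd.DataFrame(rows)
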