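"""Synthetic duet generator: coupled linear phase-correction timekeepers.

Onset model, per trial with base interval tau = 500 ms (120 bpm):

* intended phrase-1 interval of player i after beat n (n = 1..6):
  ``T_i(n) = tau + kappa * (tau*_i - tau) * n/7 + delta_i``
  where ``tau*_i`` is the cued second-phrase interval (400 ms fast / 625 ms
  slow) and ``delta_i ~ N(0, sigma_fam^2)`` only in familiar trials;
* first onsets ``t_i(1) = 3000 + N(0, sigma_start^2)``;
* coupling: ``t_i(n+1) = t_i(n) + T_i(n) - alpha_i * (t_i(n) - t_j(n)) + eta``
  with ``eta ~ N(0, sigma_timekeeper^2 + sigma_motor^2)``; the melody gain is
  shrunk by (1 - lambda_seg) in familiar-incongruent trials;
* phrase 2 starts at nominal 11,000 ms and evolves uncoupled at
  ``tau*_i`` + noise (the pianos are muted there).

Error trials are injected per trial with the configured probabilities:
a wrong note (one pitch moved a semitone), a mistempo second phrase (one
player stays at 500 ms), or an outlier phrase-1 interval (scaled by 0.5 or
1.8).  All randomness flows from ``DyadParams.seed``; each trial draws from
a substream keyed by its position in the design so that realisations do not
depend on trial order.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .design import DesignSpec, DyadParams, VALID_CUES

EVENT_COLUMNS = [
    "pair_id",
    "session",
    "trial_id",
    "player_role",
    "phrase",
    "position",
    "pitch",
    "onset_ms",
]

META_COLUMNS = [
    "pair_id",
    "session",
    "trial_id",
    "piece_id",
    "familiarity",
    "cue_melody",
    "cue_bass",
    "congruency",
    "condition",
    "instruction_type",
    "participant",
]

INJECTION_COLUMNS = ["inj_wrong_note", "inj_mistempo", "inj_outlier"]

_INSTRUCTION_CUES = {"UU": ("up", "up"), "DD": ("down", "down"), "UD": ("up", "down"), "DU": ("down", "up")}


def derive_congruency(cue_melody: str, cue_bass: str) -> str:
    for cue in (cue_melody, cue_bass):
        if cue not in VALID_CUES:
            raise ValueError(f"unknown cue label {cue!r}; expected one of {VALID_CUES}")
    return "C" if cue_melody == cue_bass else "I"


def participant_label(pair_id: int, session: int) -> str:
    """The unit of analysis: the pianist who plays the melody (in the
    scanner) during this session of this pair."""
    return f"p{int(pair_id):02d}s{int(session)}"


def make_trial_meta(design: DesignSpec) -> pd.DataFrame:
    """Balanced factorial trial table for every pair and session.

    Within each session every condition receives trials_per_condition / 2
    trials with instruction types balanced (congruent: UU/DD, incongruent:
    UD/DU) and pieces alternating within the familiarity level.
    """
    per_cond_session = design.trials_per_condition // 2
    n_pieces = len(design.pieces)
    rows = []
    for pair in range(1, design.n_pairs + 1):
        for session in (1, 2):
            # 4 pieces per session (cycled if the bank is small); first half
            # familiar, second half unfamiliar.
            offs = (session - 1) * 4
            session_pieces = [design.pieces[(offs + k) % n_pieces].piece_id for k in range(4)]
            fam_pieces = {"F": session_pieces[:2], "U": session_pieces[2:]}
            trial_id = 0
            for k in range(per_cond_session):
                for familiarity in ("F", "U"):
                    for congruency in ("C", "I"):
                        instr = ("UU", "DD")[k % 2] if congruency == "C" else ("UD", "DU")[k % 2]
                        cue_m, cue_b = _INSTRUCTION_CUES[instr]
                        trial_id += 1
                        # piece alternates independently of instruction type so
                        # that centering cells pool all instruction types
                        rows.append(
                            {
                                "pair_id": pair,
                                "session": session,
                                "trial_id": trial_id,
                                "piece_id": fam_pieces[familiarity][(k // 2) % 2],
                                "familiarity": familiarity,
                                "cue_melody": cue_m,
                                "cue_bass": cue_b,
                                "congruency": congruency,
                                "condition": familiarity + congruency,
                                "instruction_type": instr,
                                "participant": participant_label(pair, session),
                            }
                        )
    meta = pd.DataFrame(rows, columns=META_COLUMNS)
    return meta


# ---------------------------------------------------------------------------
# noise layout
# ---------------------------------------------------------------------------

def draw_noise(rng: np.random.Generator, n_trials: int) -> dict[str, np.ndarray]:
    """Standard-normal / uniform raw noise for ``n_trials`` trials.

    All draws are unit-scale; the onset kernel applies the SDs.  Keeping the
    layout fixed means a trial's realisation depends only on its substream,
    not on the parameter values that happen to be zero.
    """
    return {
        "start1": rng.standard_normal((n_trials, 2)),
        "delta": rng.standard_normal((n_trials, 2)),
        "eta1": rng.standard_normal((n_trials, 2, 6)),
        "start2": rng.standard_normal((n_trials, 2)),
        "eta2": rng.standard_normal((n_trials, 2, 6)),
        "u_inject": rng.uniform(size=(n_trials, 3)),
        "wrong_idx": rng.integers(0, 28, size=n_trials),
        "wrong_sign": rng.choice((-1, 1), size=n_trials),
        "mistempo_player": rng.integers(0, 2, size=n_trials),
        "outlier_player": rng.integers(0, 2, size=n_trials),
        "outlier_interval": rng.integers(0, 6, size=n_trials),
        "outlier_factor": rng.choice((0.5, 1.8), size=n_trials),
    }


def trial_rng(seed: int, trial_counter: int) -> np.random.Generator:
    """Counter-keyed per-trial substream of the root seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(trial_counter,)))


def draw_noise_per_trial(params: DyadParams, n_trials: int, first_counter: int = 0) -> dict[str, np.ndarray]:
    """Per-trial substream noise (trial-order invariant), stacked."""
    blocks = [draw_noise(trial_rng(params.seed, first_counter + i), 1) for i in range(n_trials)]
    return {k: np.concatenate([b[k] for b in blocks], axis=0) for k in blocks[0]}


# ---------------------------------------------------------------------------
# onset kernel
# ---------------------------------------------------------------------------

def _meta_arrays(meta: pd.DataFrame, design: DesignSpec) -> dict[str, np.ndarray]:
    familiar = (meta["familiarity"].to_numpy() == "F")
    congruent = (meta["congruency"].to_numpy() == "C")
    target = np.column_stack(
        [
            [design.cued_iki_ms(c) for c in meta["cue_melody"]],
            [design.cued_iki_ms(c) for c in meta["cue_bass"]],
        ]
    )
    return {"familiar": familiar, "congruent": congruent, "target_iki": target}


def onsets_from_noise(
    params: DyadParams,
    design: DesignSpec,
    meta: pd.DataFrame,
    noise: Mapping[str, np.ndarray],
) -> tuple[np.ndarray, pd.DataFrame]:
    """Pure kernel: (n_trials, 2 players, 14 positions) onset times in ms.

    Player axis: 0 = melody (scanner pianist), 1 = bass.  Returns the onset
    array and the per-trial injection log.
    """
    n = len(meta)
    arrs = _meta_arrays(meta, design)
    familiar, congruent, target = arrs["familiar"], arrs["congruent"], arrs["target_iki"]
    tau = design.base_iki_ms
    npp = design.notes_per_phrase

    delta = noise["delta"] * params.sigma_fam * familiar[:, None]
    beat = np.arange(1, npp)  # interval after beat n, n = 1..6
    intended = tau + params.kappa * (target - tau)[:, :, None] * (beat / npp) + delta[:, :, None]

    alpha = np.empty((n, 2))
    seg = familiar & ~congruent
    alpha[:, 0] = params.alpha_melody * np.where(seg, 1.0 - params.lambda_seg, 1.0)
    alpha[:, 1] = params.alpha_bass

    onsets = np.empty((n, 2, 2 * npp))
    onsets[:, :, 0] = design.first_onset_ms + noise["start1"] * params.sigma_start
    eta1 = noise["eta1"] * params.sigma_interval
    for i in range(npp - 1):
        asyn = onsets[:, 0, i] - onsets[:, 1, i]
        onsets[:, 0, i + 1] = onsets[:, 0, i] + intended[:, 0, i] - alpha[:, 0] * asyn + eta1[:, 0, i]
        onsets[:, 1, i + 1] = onsets[:, 1, i] + intended[:, 1, i] + alpha[:, 1] * asyn + eta1[:, 1, i]

    # --- phrase 2: uncoupled, cued tempo ---
    inj_mistempo = noise["u_inject"][:, 1] < params.p_mistempo
    tau2 = target.copy()
    tau2[inj_mistempo, noise["mistempo_player"][inj_mistempo]] = tau
    start2 = design.phrase2_onset_ms + noise["start2"] * params.sigma_start
    incr = tau2[:, :, None] + noise["eta2"] * params.sigma_interval
    onsets[:, :, npp] = start2
    onsets[:, :, npp + 1 :] = start2[:, :, None] + np.cumsum(incr, axis=2)

    # --- outlier phrase-1 interval ---
    inj_outlier = noise["u_inject"][:, 2] < params.p_outlier
    for t in np.flatnonzero(inj_outlier):
        p = noise["outlier_player"][t]
        j = noise["outlier_interval"][t]
        iki = onsets[t, p, j + 1] - onsets[t, p, j]
        onsets[t, p, j + 1 : npp] += (noise["outlier_factor"][t] - 1.0) * iki

    inj_wrong = noise["u_inject"][:, 0] < params.p_wrong_note
    log = pd.DataFrame(
        {
            "inj_wrong_note": inj_wrong,
            "inj_mistempo": inj_mistempo,
            "inj_outlier": inj_outlier,
        },
        index=meta.index,
    )
    return onsets, log


def _pitch_bank(design: DesignSpec) -> dict[str, np.ndarray]:
    return {
        s.piece_id: np.array([s.melody_pitches, s.bass_pitches], dtype=np.int64) for s in design.pieces
    }


def pitches_for_trials(
    design: DesignSpec, meta: pd.DataFrame, noise: Mapping[str, np.ndarray], log: pd.DataFrame
) -> np.ndarray:
    """(n_trials, 2, 14) pitch array with wrong-note injections applied."""
    bank = _pitch_bank(design)
    pitches = np.stack([bank[p] for p in meta["piece_id"]])
    wrong = log["inj_wrong_note"].to_numpy()
    for t in np.flatnonzero(wrong):
        player, pos = divmod(int(noise["wrong_idx"][t]), 14)
        sign = int(noise["wrong_sign"][t])
        p = pitches[t, player, pos] + sign
        if not 0 <= p <= 127:
            p = pitches[t, player, pos] - sign
        pitches[t, player, pos] = p
    return pitches


def events_from_arrays(meta: pd.DataFrame, onsets: np.ndarray, pitches: np.ndarray) -> pd.DataFrame:
    """Long-format keystroke event table (one row per key press)."""
    n = len(meta)
    npp = onsets.shape[2] // 2
    reps = 2 * 2 * npp
    phrase = np.tile(np.repeat([1, 2], npp), 2)
    position = np.tile(np.arange(1, npp + 1), 4)
    events = pd.DataFrame(
        {
            "pair_id": np.repeat(meta["pair_id"].to_numpy(), reps),
            "session": np.repeat(meta["session"].to_numpy(), reps),
            "trial_id": np.repeat(meta["trial_id"].to_numpy(), reps),
            "player_role": np.tile(np.repeat(["melody", "bass"], 2 * npp), n),
            "phrase": np.tile(phrase, n),
            "position": np.tile(position, n),
            "pitch": pitches.reshape(-1),
            "onset_ms": onsets.reshape(-1),
        },
        columns=EVENT_COLUMNS,
    )
    return events


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def simulate_trial(
    params: DyadParams,
    design: DesignSpec,
    trial_meta: Mapping[str, object],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one trial; returns its 28-row keystroke event table."""
    meta = pd.DataFrame([dict(trial_meta)])
    if meta.loc[0, "familiarity"] not in ("F", "U"):
        raise ValueError(f"familiarity must be 'F' or 'U', got {meta.loc[0, 'familiarity']!r}")
    meta["congruency"] = derive_congruency(str(meta.loc[0, "cue_melody"]), str(meta.loc[0, "cue_bass"]))
    rng = rng if rng is not None else trial_rng(params.seed, 0)
    noise = draw_noise(rng, 1)
    onsets, log = onsets_from_noise(params, design, meta, noise)
    pitches = pitches_for_trials(design, meta, noise, log)
    return events_from_arrays(meta, onsets, pitches)


def simulate_dataset(
    params: DyadParams, design: DesignSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full factorial dataset.

    Returns ``(events, meta)``; ``meta`` carries the simulator's injection
    log in boolean ``inj_*`` columns (bookkeeping for QC validation, not part
    of the experimental design).  Deterministic given ``params.seed``: each
    trial uses a substream keyed by its row index in the design table.
    """
    meta = make_trial_meta(design)
    noise = draw_noise_per_trial(params, len(meta))
    onsets, log = onsets_from_noise(params, design, meta, noise)
    pitches = pitches_for_trials(design, meta, noise, log)
    events = events_from_arrays(meta, onsets, pitches)
    meta = pd.concat([meta, log], axis=1)
    return events, meta
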