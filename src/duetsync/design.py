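"""Experimental-design and simulator-parameter types.

The paradigm: two pianists jointly perform short two-phrase duets.  A visual
cue tells each player the tempo of the *second* phrase (fast = 150 bpm or
slow = 96 bpm); the first phrase is always played together at the base tempo
of 120 bpm, and the second phrase is played solo (the pianos are muted, so
the players are uncoupled there).  Cues are either congruent (both fast or
both slow) or incongruent between the players.  Anticipation of the upcoming
tempo leaks into first-phrase timing, which is the behavioural effect the
simulator reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MS_PER_MIN = 60_000.0

#: cue label -> second-phrase tempo label
CUE_TEMPO = {"up": "fast", "down": "slow"}

VALID_CUES = ("up", "down")
VALID_FAMILIARITY = ("F", "U")
CONDITIONS = ("FC", "FI", "UC", "UI")
INSTRUCTION_TYPES = ("UU", "DD", "UD", "DU")


def bpm_to_iki(bpm: float) -> float:
    """Quarter-note inter-keystroke interval (ms) at a given tempo."""
    return MS_PER_MIN / bpm


@dataclass(frozen=True)
class ScoreSpec:
    """One duet piece: 14 quarter notes per hand, 7 per phrase.

    Positions 1-7 form phrase 1, positions 8-14 phrase 2; the two bars
    between the phrases are a rest and carry no keystrokes.
    """

    piece_id: str
    melody_pitches: tuple[int, ...]
    bass_pitches: tuple[int, ...]

    def __post_init__(self) -> None:
        for name, pitches in (("melody", self.melody_pitches), ("bass", self.bass_pitches)):
            if len(pitches) != 14:
                raise ValueError(
                    f"{self.piece_id}: {name} must have 14 pitches (7 per phrase), got {len(pitches)}"
                )
            if any(not (0 <= p <= 127) for p in pitches):
                raise ValueError(f"{self.piece_id}: {name} pitches must be MIDI numbers 0-127")

    def pitches(self, role: str) -> tuple[int, ...]:
        if role == "melody":
            return self.melody_pitches
        if role == "bass":
            return self.bass_pitches
        raise ValueError(f"unknown role {role!r}")


def default_scores(n_pieces: int = 8) -> tuple[ScoreSpec, ...]:
    """Deterministic bank of simple diatonic two-phrase duet scores."""
    c_major = (0, 2, 4, 5, 7, 9, 11)
    pieces = []
    for k in range(n_pieces):
        melody = tuple(60 + c_major[(k + 2 * i) % 7] + 12 * (((k + i) // 7) % 2) for i in range(14))
        bass = tuple(36 + c_major[(3 * k + i) % 7] for i in range(14))
        pieces.append(ScoreSpec(piece_id=f"piece{k + 1:02d}", melody_pitches=melody, bass_pitches=bass))
    return tuple(pieces)


@dataclass(frozen=True)
class DesignSpec:
    """Factorial session layout: 2 (familiarity) x 2 (tempo congruency).

    Each pair of pianists plays two sessions with fixed roles within a
    session (the scanner pianist plays the melody) and swapped roles between
    sessions.  ``trials_per_condition`` counts trials per pair across both
    sessions; the default 32 gives the canonical 128 trials per pair.
    """

    n_pairs: int = 19
    trials_per_condition: int = 32
    pieces: tuple[ScoreSpec, ...] = field(default_factory=default_scores)
    base_tempo_bpm: float = 120.0
    fast_bpm: float = 150.0
    slow_bpm: float = 96.0
    notes_per_phrase: int = 7
    cue_ms: float = 1000.0
    metronome_beats: int = 4

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.trials_per_condition < 4 or self.trials_per_condition % 4:
            raise ValueError(
                "trials_per_condition must be a positive multiple of 4 "
                "(balanced instruction types across 2 sessions)"
            )
        if len(self.pieces) < 2:
            raise ValueError("need at least 2 pieces (one familiar, one unfamiliar per session)")
        if self.notes_per_phrase != 7:
            raise ValueError("the paradigm uses 7 quarter notes per phrase")

    @property
    def base_iki_ms(self) -> float:
        return bpm_to_iki(self.base_tempo_bpm)  # 500 ms at 120 bpm

    @property
    def fast_iki_ms(self) -> float:
        return bpm_to_iki(self.fast_bpm)  # 400 ms at 150 bpm

    @property
    def slow_iki_ms(self) -> float:
        return bpm_to_iki(self.slow_bpm)  # 625 ms at 96 bpm

    @property
    def metronome_ms(self) -> float:
        """Count-in duration: 4 metronome beats at the base tempo (2,000 ms)."""
        return self.metronome_beats * self.base_iki_ms

    @property
    def phrase_beats(self) -> int:
        """Beats per phrase including the trailing quarter rest (8)."""
        return self.notes_per_phrase + 1

    @property
    def first_onset_ms(self) -> float:
        """Nominal time of the first keystroke (cue + count-in)."""
        return self.cue_ms + self.metronome_ms

    @property
    def phrase2_onset_ms(self) -> float:
        """Nominal time of the first keystroke of phrase 2.

        Phrase 1 (8 beats) and the two-bar pause (8 beats) both run at the
        base tempo.
        """
        return self.first_onset_ms + 2 * self.phrase_beats * self.base_iki_ms

    def cued_iki_ms(self, cue: str) -> float:
        """Second-phrase interval implied by a cue label ('up' or 'down')."""
        if cue not in CUE_TEMPO:
            raise ValueError(f"unknown cue label {cue!r}; expected one of {VALID_CUES}")
        return self.fast_iki_ms if cue == "up" else self.slow_iki_ms

    def trials_per_pair(self) -> int:
        return 4 * self.trials_per_condition


def tempo_templates(design: DesignSpec) -> dict[str, float]:
    """Constant IKI templates (ms) used by the tempo goodness-of-fit check."""
    return {
        "fast": design.fast_iki_ms,
        "slow": design.slow_iki_ms,
        "none": design.base_iki_ms,
    }


def nominal_trial_duration(cued_tempo: str, design: DesignSpec | None = None) -> float:
    """Nominal trial span in ms for a given second-phrase tempo label.

    cue (1,000 ms) + metronome count-in (4 beats at 120 bpm) + phrase 1
    (8 beats at 120 bpm) + pause (8 beats at 120 bpm) + phrase 2 (8 beats at
    the cued tempo).  'fast' -> 14,200 ms; 'slow' -> 16,000 ms.
    """
    design = design or DesignSpec()
    templates = tempo_templates(design)
    if cued_tempo not in templates:
        raise ValueError(f"unknown tempo label {cued_tempo!r}; expected one of {sorted(templates)}")
    fixed = design.cue_ms + design.metronome_ms + 2 * design.phrase_beats * design.base_iki_ms
    return fixed + design.phrase_beats * templates[cued_tempo]


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value}")


@dataclass(frozen=True)
class DyadParams:
    """Generative parameters of the coupled linear phase-correction dyad.

    Each player is a first-order linear phase corrector: their next interval
    is the intended interval minus a gain (alpha) times the current signed
    asynchrony to the partner.  ``lambda_seg`` models self-other segregation:
    in familiar-incongruent trials the melody (scanner) player's gain is
    multiplied by (1 - lambda_seg).  ``kappa`` scales the anticipatory drift
    of intended phrase-1 intervals toward the cued second-phrase tempo, and
    ``sigma_fam`` is the SD of a per-trial per-player tempo-signature offset
    applied only in familiar trials.
    """

    alpha_melody: float = 0.15
    alpha_bass: float = 0.30
    lambda_seg: float = 0.5
    kappa: float = 0.04
    sigma_timekeeper: float = 10.0
    sigma_motor: float = 8.0
    sigma_fam: float = 6.0
    sigma_start: float = 15.0
    p_wrong_note: float = 0.05
    p_mistempo: float = 0.03
    p_outlier: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_melody", "alpha_bass"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        _check_prob("lambda_seg", self.lambda_seg)
        _check_nonneg("kappa", self.kappa)
        for name in ("sigma_timekeeper", "sigma_motor", "sigma_fam", "sigma_start"):
            _check_nonneg(name, getattr(self, name))
        for name in ("p_wrong_note", "p_mistempo", "p_outlier"):
            _check_prob(name, getattr(self, name))

    @property
    def sigma_interval(self) -> float:
        """SD of the combined timekeeper + motor noise per interval (ms)."""
        return float((self.sigma_timekeeper**2 + self.sigma_motor**2) ** 0.5)

    def noiseless(self) -> bool:
        return (
            self.sigma_timekeeper == self.sigma_motor == self.sigma_fam == self.sigma_start == 0.0
        )
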