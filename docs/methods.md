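# Methods

## The paradigm being modelled

Two pianists jointly perform short two-phrase duets at a base tempo of 120
bpm (quarter-note interval τ = 500 ms).  One pianist (the *melody* player,
inside an MR scanner in the original setting) plays the right hand, the
partner plays the bass line.  Each trial begins with a visual cue (1,000 ms)
telling each player the tempo of the *second* phrase — fast (150 bpm, 400 ms
intervals) or slow (96 bpm, 625 ms) — followed by a four-beat metronome
count-in (2,000 ms).  Phrase 1 (7 quarter notes + a quarter rest) is played
together at 120 bpm, a two-bar pause follows, and phrase 2 is played solo
(the pianos are muted, so the players are uncoupled there).  Cues are
congruent (both fast / both slow) or incongruent, and familiarity is
manipulated by whether a player has practiced the partner's part.  The key
behavioural phenomenon: anticipation of the upcoming tempo leaks into
phrase-1 timing, so incongruent cues create systematic microsecond-to-
millisecond-scale asynchronies even though both players nominally keep 120
bpm.

## The generative model (synthetic data)

Each player is a first-order linear phase-correcting timekeeper — the
standard sensorimotor-synchronization model of dyadic tapping.  For player
*i* with partner *j*, phrase-1 onsets follow

    t_i(n+1) = t_i(n) + T_i(n) − α_i (t_i(n) − t_j(n)) + η,
    T_i(n)   = τ + κ (τ*_i − τ) n/7 + δ_i,          n = 1..6,

with first onsets `t_i(1) = 3000 + N(0, σ_start²)` ms.  Here

* `α_i` is the phase-correction gain (default melody 0.15, bass 0.30 — the
  partner outside the scanner adapts more, producing the observed lag +1 >
  lag −1 asymmetry);
* `λ` (default 0.5) multiplies the melody gain by (1 − λ) in
  familiar-incongruent trials, modelling self–other *segregation*: when a
  familiar motor simulation of the partner's part clashes with incongruent
  feedback, the scanner pianist down-weights the partner;
* `κ` (default 0.04) scales a linear anticipatory ramp of the intended
  interval toward the cued second-phrase interval `τ*_i ∈ {400, 625}` ms;
  any monotone ramp reproduces the early-phrase asynchrony pattern — the
  linear form is chosen for analytic tractability (the noiseless recursion
  is verified against a hand-written oracle);
* `δ_i ~ N(0, σ_fam²)` (default σ_fam = 6 ms) is a per-trial per-player
  tempo-signature offset applied only in familiar trials, modelling reliance
  on one's own internal timing signature — it raises the within-trial SD of
  asynchronies in familiar conditions;
* `η ~ N(0, σ_tk² + σ_motor²)` (defaults 10 and 8 ms) folds central
  timekeeper and peripheral motor noise into one Gaussian increment per
  interval.  A full two-source decomposition with lag-1 motor covariance is
  deliberately out of scope; none of the implemented metrics depend on it.

Phrase 2 starts at nominal 11,000 ms and evolves uncoupled at `τ*_i` plus
the same interval noise.  Error trials are injected independently per trial:
a wrong note (one pitch moved ±1 semitone, p = 0.05), a wrong-tempo second
phrase (one player stays at 500 ms, p = 0.03), and an outlier phrase-1
interval (scaled by 0.5 or 1.8, p = 0.01).  Defaults put the simulated
condition means in the vicinity of the reported behavioural values
(|asynchrony| means of a few ms, asynchrony SDs in the high teens, and
roughly 70–85 % trial retention); they are deliberately not tuned to
reproduce any printed mean exactly.

Randomness: one root seed; each trial of `simulate_dataset` draws from a
substream keyed by its position in the design table, so realisations do not
depend on trial order or on which other trials are generated.  The
vectorized replicate engine (`replicates.py`), used for calibration studies,
draws each dataset from a single seeded stream instead; both paths share the
same pure onset and summary kernels and are cross-checked for equality in
the tests.

What the generator does **not** emulate: expressive dynamics, pedaling,
polyphony, serially correlated (drifting) tempo within phrase 1, or stable
individual differences in adaptation gain across trials.  The last point
matters for interpretation: between-participant variance of the
lag-correlation summaries is purely sampling noise here, which is larger
than what stable individual adaptation styles produce in real data (see
"Calibration results" below).

## Analysis pipeline

**QC** mirrors the three-stage exclusion logic, in order: (1) any wrong key
(either player, either phrase, pitch compared against the score) excludes
the trial; (2) each player's six phrase-2 intervals are classified to the
constant-IKI template (400/625/500 ms) with minimal mean squared error — a
trial is excluded when either player's best-fitting tempo differs from that
player's instruction, with exact MSE ties resolved in the trial's favour if
the instruction is among the tied minima (only a *demonstrably* better-
fitting wrong tempo excludes); (3) after an optional technical-error flag,
trials containing a phrase-1 interval strictly outside the pooled 1st–99th
percentile band (both players, all surviving trials, linear-interpolation
percentiles) are removed.  The percentile pool is computed on survivors of
the earlier stages only; freezing the band makes the filter idempotent.
With fewer than 100 pooled intervals the filter is skipped with a warning.
Note a consequence of strict percentile trimming on continuous data: even
injection-free noisy datasets lose ≈ 2 % of trials.

**Metrics.**  Signed asynchrony a(n) = melody onset − bass onset per
keystroke, mean-centered per keystroke position and piece within each
participant-session (this removes piece/position difficulty without mixing
dyads; the single-trial-cell degenerate case centers to exactly 0 and is
flagged).  Accuracy: per participant and tempo-instruction type (UU, DD,
UD, DU) the signed asynchronies of keystrokes 1–7 across trials are
averaged, absolute values of these means are then averaged into the
condition value (congruent ← {UU, DD}, incongruent ← {UD, DU}).  Averaging
signed values before taking |·| is the primary definition; per-trial
absolute and per-trial-mean-first variants are available as configuration
switches for sensitivity analysis (the pooling variants coincide for
balanced designs).  Stability: per-trial SD of the seven asynchronies (n−1
denominator), averaged across a condition's trials.  Adaptation: the two
players' six IKIs are cross-correlated per trial with the melody (scanner)
pianist as reference — lag −1 pairs melody IKI n with bass IKI n−1 (5
pairs; the scanner pianist following the partner), lag +1 the converse,
lag 0 all six aligned pairs.  Coefficients are Fisher z-transformed (atanh,
r clipped to ±(1−10⁻¹²)) before averaging; zero-variance trials are treated
as missing, never as 0.  The unit of analysis is the pianist, attributed to
the session in which they played the melody, giving 2 × n_pairs behavioural
participants.

**Inference.**  All factors have 2 levels, so the repeated-measures ANOVA
is computed by paired contrasts: each main effect and interaction is a
per-participant ±1-coded contrast score tested against zero, F(1, n−1) =
t², with partial eta squared F/(F + n − 1).  Sphericity is trivially exact
at two levels and the implementation is verified against a full
sum-of-squares decomposition oracle and against pingouin.  Paired t tests
report Cohen's d_z = t/√n (this definition exactly reproduces the published
effect sizes from the published t values).  Pearson correlations report r,
two-tailed p and R².  Two independent correlations are compared with the
Fisher r-to-z test, z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)); both
one- and two-tailed p values are reported because the original report used
the one-tailed value.  Degenerate inputs (zero contrast or difference
variance) yield infinite/NaN statistics with a diagnostic note rather than
a silent 0.

**Cluster-extent threshold.**  Null volumes are i.i.d. standard normal on
the full rectangular grid (no mask), Gaussian-smoothed (σ = FWHM/(2√(2 ln 2))
per axis in voxel units), re-standardized to unit variance — without
re-standardization smoothing silently deflates the suprathreshold rate —
and thresholded one-tailed at the (1 − p_voxel) normal quantile.  Cluster
connectivity defaults to 18 (face + edge, SPM-like) and is configurable
(6/18/26).  The extent threshold is the smallest integer k whose empirical
max-cluster exceedance falls below the family-wise α; minimality and
monotonicity in FWHM, voxel p and α are tested.  On the full 102×102×66
box at 2 mm with FWHM 8 mm and voxel p = 0.001 this yields a threshold of
roughly 100 voxels — the same order of magnitude as the published 33
resampled voxels, with the remaining gap attributable to the original
simulation's unstated grid/masking and connectivity choices (simulating at
the coarser acquisition grid and converting cluster volumes to resampled
voxels gives smaller thresholds).

## Calibration results the test suite computes

* Type-I error of each 2 × 2 effect on null simulations (all effect
  parameters zero, 38 participants, 1,000 replicate datasets at 16
  trials/condition) is within 0.05 ± 0.02.
* Power over 200 replicate datasets at the default design (38 participants,
  32 trials/condition/pair): the TEMPO effect on |asynchrony| and the
  FAMILIARITY effect on asynchrony SD are detected essentially always
  (≈ 1.00 and ≈ 0.99).  The FAMILIARITY × TEMPO interaction on lag −1 z is
  detected in only ≈ 0.15–0.20 of replicates: a per-trial lag correlation
  estimated from 5 IKI pairs has z-SD ≈ 0.7, so a participant-condition
  mean over 16 trials carries SD ≈ 0.18, and an interaction of ≈ 0.07 in r
  units (the size of the published FC–FI gap) is simply not reliably
  detectable under this noise model.  Real data evidently has smaller
  between-participant variance (stable individual adaptation styles) than
  the white-noise timekeeper produces; the corresponding acceptance test is
  left failing rather than inflating the generative effect.
* Directional recovery at the trial level (two-sample tests at α = 0.01,
  several thousand retained trials per condition): |asynchrony| incongruent
  > congruent, asynchrony SD familiar > unfamiliar, lag −1 z lower in FI
  than FC with no congruency effect in unfamiliar conditions, and lag +1 >
  lag −1.

## Problem sizes used by tests and the acceptance script

Chosen as the package's own defaults for a single-core run: the effect-
recovery dataset uses 66 pairs × 64 trials/condition (≈ 3,000 retained
trials per cell); the calibration studies use the replicate engine (1,000
null and 200 effect-on datasets); Monte Carlo thresholds use 300 iterations
in tests and 1,000 in the acceptance script.

## Known limitations

* The generative model is a deliberately minimal linear phase-correction
  process; it makes no mechanistic claim about the performers.
* Lag-0 cross-correlations come out slightly negative under this model
  (opposite-signed reactions of the two players to the same asynchrony,
  with no shared tempo drift to induce positive coupling); the original
  data show positive lag-0 coupling.  No analysis here depends on the
  lag-0 sign.
* MIDI ingestion supports Standard MIDI Files (format 0/1) with tick-based
  timing and tempo maps; SMPTE division, real-time capture and velocity
  analysis are out of scope.
* The group-level behavioural means of the original study are not
  reproducible from first principles (they depend on the unavailable raw
  recordings); the simulator targets their direction and rough magnitude
  only.
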