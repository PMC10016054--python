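import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_lag_crosscorr, brute_pearson
from duetsync import (
    accuracy_summary,
    adaptation_summary,
    compute_asynchronies,
    condition_summary,
    lag_crosscorr,
    mean_center,
    stability_summary,
    trial_lag_correlations,
)
from duetsync.metrics import TRIAL_KEY
from duetsync.replicates import _MetaCodes, summaries_from_onsets, summary_frame
from duetsync.simulate import draw_noise_per_trial, make_trial_meta, onsets_from_noise
from test_qc import build_trial


def two_player_trial(trial_id, melody, bass, **kw):
    return build_trial(trial_id, melody, bass, **kw)


class TestAsynchrony:
    def test_definition_melody_minus_bass(self):
        ev = two_player_trial(
            1,
            [3000, 3500, 4000, 4500, 5000, 5500, 6000],
            [2995, 3505, 4000, 4500, 5000, 5500, 6000],
        )
        a = compute_asynchronies(ev)
        assert list(a["asynchrony"][:2]) == [5.0, -5.0]
        assert (a["asynchrony"][2:] == 0.0).all()

    def test_identical_onsets_all_zero(self):
        ev = two_player_trial(1, [3000 + 500 * i for i in range(7)], None)
        assert (compute_asynchronies(ev)["asynchrony"] == 0.0).all()

    def test_missing_position_skips_trial_with_warning(self):
        ev = two_player_trial(1, [3000 + 500 * i for i in range(7)], None)
        ev = ev.drop(index=ev.index[3])
        with pytest.warns(UserWarning, match="missing"):
            a = compute_asynchronies(ev)
        assert a.empty

    def test_role_swap_antisymmetry(self, small_dataset):
        """Relabelling melody<->bass negates every signed asynchrony and
        leaves |mean| and SD unchanged."""
        ev, _ = small_dataset
        swapped = ev.copy()
        swapped["player_role"] = swapped["player_role"].map({"melody": "bass", "bass": "melody"})
        a = compute_asynchronies(ev).set_index(TRIAL_KEY + ["position"])
        b = compute_asynchronies(swapped).set_index(TRIAL_KEY + ["position"])
        np.testing.assert_allclose(a["asynchrony"], -b.loc[a.index, "asynchrony"])
        sd_a = a.groupby(TRIAL_KEY)["asynchrony"].std()
        sd_b = b.groupby(TRIAL_KEY)["asynchrony"].std()
        np.testing.assert_allclose(sd_a, sd_b)


class TestCentering:
    def test_two_point_cell(self):
        meta = pd.DataFrame(
            {
                "pair_id": [1, 1],
                "session": [1, 1],
                "trial_id": [1, 2],
                "piece_id": ["p", "p"],
            }
        )
        asyn = pd.DataFrame(
            {
                "pair_id": [1, 1],
                "session": [1, 1],
                "trial_id": [1, 2],
                "position": [1, 1],
                "asynchrony": [4.0, 6.0],
            }
        )
        c = mean_center(asyn, meta)
        assert list(c["asynchrony_centered"]) == [-1.0, 1.0]
        assert not c["single_trial_cell"].any()

    def test_identical_trials_center_to_zero(self):
        trials = [two_player_trial(i, [3000 + 500 * j + 3 for j in range(7)], [3000 + 500 * j for j in range(7)]) for i in range(1, 4)]
        ev = pd.concat(trials, ignore_index=True)
        meta = pd.DataFrame({"pair_id": 1, "session": 1, "trial_id": [1, 2, 3], "piece_id": "p"})
        c = mean_center(compute_asynchronies(ev), meta)
        assert (c["asynchrony_centered"] == 0.0).all()

    def test_cell_means_vanish(self, small_dataset):
        ev, meta = small_dataset
        c = mean_center(compute_asynchronies(ev), meta)
        cell_means = c.groupby(["pair_id", "session", "piece_id", "position"])[
            "asynchrony_centered"
        ].mean()
        assert np.abs(cell_means).max() < 1e-9


class TestAccuracyAndStability:
    @staticmethod
    def _centered_with_meta(small_dataset):
        ev, meta = small_dataset
        return mean_center(compute_asynchronies(ev), meta), meta

    def test_all_zero_asynchronies_give_zero(self):
        trials = [two_player_trial(i, [3000 + 500 * j for j in range(7)], None) for i in range(1, 5)]
        ev = pd.concat(trials, ignore_index=True)
        meta = pd.DataFrame(
            {
                "pair_id": 1,
                "session": 1,
                "trial_id": [1, 2, 3, 4],
                "piece_id": "p",
                "participant": "p01s1",
                "familiarity": ["F", "F", "U", "U"],
                "congruency": ["C", "I", "C", "I"],
                "condition": ["FC", "FI", "UC", "UI"],
                "instruction_type": ["UU", "UD", "DD", "DU"],
            }
        )
        c = mean_center(compute_asynchronies(ev), meta)
        acc = accuracy_summary(c, meta)
        assert (acc["mean_abs_async"] == 0.0).all()

    def test_plus_minus_six_instruction_means(self):
        """Instruction means +6 (UD) and -6 (DU) yield an incongruent
        condition value of 6 ms."""
        rows = []
        for trial, (instr, off) in enumerate([("UD", 6.0), ("DU", -6.0)], start=1):
            rows.append(
                two_player_trial(trial, [3000 + 500 * j + off for j in range(7)], [3000 + 500 * j for j in range(7)])
            )
        ev = pd.concat(rows, ignore_index=True)
        meta = pd.DataFrame(
            {
                "pair_id": 1,
                "session": 1,
                "trial_id": [1, 2],
                "piece_id": ["p1", "p2"],  # distinct pieces so centering keeps the offsets
                "participant": "p01s1",
                "familiarity": "U",
                "congruency": "I",
                "condition": "UI",
                "instruction_type": ["UD", "DU"],
            }
        )
        centered = compute_asynchronies(ev)
        centered["asynchrony_centered"] = centered["asynchrony"]  # bypass centering
        acc = accuracy_summary(centered, meta)
        assert acc.loc[acc["condition"] == "UI", "mean_abs_async"].item() == pytest.approx(6.0)

    def test_pooling_variants_agree_on_balanced_data(self, small_dataset):
        c, meta = self._centered_with_meta(small_dataset)
        a1 = accuracy_summary(c, meta, pool="keystrokes")
        a2 = accuracy_summary(c, meta, pool="trials")
        np.testing.assert_allclose(a1["mean_abs_async"], a2["mean_abs_async"], atol=1e-9)

    def test_per_trial_abs_variant_is_larger(self, small_dataset):
        """|.| before averaging can only increase the condition value."""
        c, meta = self._centered_with_meta(small_dataset)
        a_signed = accuracy_summary(c, meta).set_index(["participant", "condition"])
        a_abs = accuracy_summary(c, meta, per_trial_abs=True).set_index(["participant", "condition"])
        assert (a_abs["mean_abs_async"] + 1e-12 >= a_signed["mean_abs_async"]).all()

    def test_alternating_series_sd(self):
        """a = [5,-5,5,-5,5,-5,5]: mean 5/7, SS 8400/49, SD = 5.345 ms."""
        melody = np.cumsum([3000] + [500] * 6) + np.array([5, -5, 5, -5, 5, -5, 5])
        ev = two_player_trial(1, melody, np.cumsum([3000] + [500] * 6))
        meta = pd.DataFrame(
            {"pair_id": [1], "session": [1], "trial_id": [1], "piece_id": "p", "participant": "x", "condition": "FC"}
        )
        centered = compute_asynchronies(ev)
        centered["asynchrony_centered"] = centered["asynchrony"]
        stab = stability_summary(centered, meta)
        assert stab["mean_sd_async"].item() == pytest.approx(math.sqrt(8400 / 49 / 6), abs=1e-9)
        assert stab["mean_sd_async"].item() == pytest.approx(5.345, abs=5e-4)

    def test_constant_series_zero_sd(self):
        ev = two_player_trial(1, [3000 + 500 * j + 4 for j in range(7)], [3000 + 500 * j for j in range(7)])
        meta = pd.DataFrame(
            {"pair_id": [1], "session": [1], "trial_id": [1], "piece_id": "p", "participant": "x", "condition": "FC"}
        )
        centered = compute_asynchronies(ev)
        centered["asynchrony_centered"] = centered["asynchrony"]
        assert stability_summary(centered, meta)["mean_sd_async"].item() == 0.0


class TestLagCrossCorrelation:
    def test_identical_vectors_lag0(self):
        r, z = lag_crosscorr([480, 510, 495, 520, 490, 505], [480, 510, 495, 520, 490, 505], 0)
        assert r == pytest.approx(1.0)
        assert np.isfinite(z)

    def test_shift_construction_fixes_sign_convention(self):
        """bass(n-1) = melody(n) exactly -> lag -1 r = 1 (the scanner pianist
        mirrors the partner's previous interval)."""
        melody = np.array([480.0, 510, 495, 520, 490, 505])
        bass = np.empty(6)
        bass[:-1] = melody[1:]
        bass[-1] = 555.0
        r, _ = lag_crosscorr(melody, bass, -1)
        assert r == pytest.approx(1.0)
        r_plus, _ = lag_crosscorr(bass, melody, +1)
        assert r_plus == pytest.approx(1.0)

    def test_reverse_order_matches_brute_force(self):
        melody = [480.0, 510, 495, 520, 490, 505]
        bass = melody[::-1]
        r, _ = lag_crosscorr(melody, bass, 0)
        assert r == pytest.approx(brute_pearson(melody, bass), abs=1e-12)

    def test_zero_variance_is_missing_not_zero(self):
        r, z = lag_crosscorr([500.0] * 6, [480, 510, 495, 520, 490, 505], 0)
        assert math.isnan(r) and math.isnan(z)

    def test_oracle_equivalence_all_lags(self):
        """Vectorized r equals the double-loop Pearson oracle on 1,000
        random IKI vectors at every lag."""
        rng = np.random.default_rng(8)
        for _ in range(1000):
            m = rng.normal(500, 25, 6)
            b = rng.normal(500, 25, 6)
            for lag in (-1, 0, 1):
                r, _ = lag_crosscorr(m, b, lag)
                assert r == pytest.approx(brute_lag_crosscorr(m, b, lag), abs=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(
        scale=st.floats(0.01, 100.0),
        offset=st.floats(-1000.0, 1000.0),
        lag=st.sampled_from([-1, 0, 1]),
    )
    def test_affine_invariance(self, scale, offset, lag):
        rng = np.random.default_rng(3)
        m = rng.normal(500, 20, 6)
        b = rng.normal(500, 20, 6)
        r1, z1 = lag_crosscorr(m, b, lag)
        r2, z2 = lag_crosscorr(m * scale + offset, b, lag)
        assert r2 == pytest.approx(r1, abs=1e-9)
        assert z2 == pytest.approx(z1, abs=1e-7)

    def test_bad_input_rejected(self):
        with pytest.raises(ValueError, match="length-6"):
            lag_crosscorr([1, 2, 3], [1, 2, 3], 0)
        with pytest.raises(ValueError, match="lag"):
            lag_crosscorr([1.0] * 6, [1.0] * 6, 2)


class TestSummaries:
    def test_constant_r_condition_mean_is_atanh(self):
        lags = pd.DataFrame(
            {
                "pair_id": 1,
                "session": 1,
                "trial_id": [1, 2, 3],
                "z_lag_m1": np.arctanh(0.5),
                "z_lag_0": np.arctanh(0.5),
                "z_lag_p1": np.arctanh(0.5),
            }
        )
        meta = pd.DataFrame(
            {"pair_id": 1, "session": 1, "trial_id": [1, 2, 3], "participant": "x", "condition": "FC"}
        )
        out = adaptation_summary(lags, meta)
        assert out["z_lag_m1"].item() == pytest.approx(0.5493, abs=1e-4)

    def test_condition_summary_shape(self, small_dataset):
        ev, meta = small_dataset
        cs = condition_summary(ev, meta)
        n_participants = meta["participant"].nunique()
        assert len(cs) == n_participants * 4
        assert set(cs["condition"]) == {"FC", "FI", "UC", "UI"}

    def test_fast_path_matches_pandas_path(self, clean_params):
        """The vectorized replicate engine reproduces the DataFrame pipeline
        to numerical precision."""
        from duetsync import DesignSpec

        design = DesignSpec(n_pairs=3, trials_per_condition=8)
        meta = make_trial_meta(design)
        noise = draw_noise_per_trial(clean_params, len(meta))
        onsets, log = onsets_from_noise(clean_params, design, meta, noise)
        from duetsync.simulate import events_from_arrays, pitches_for_trials

        events = events_from_arrays(meta, onsets, pitches_for_trials(design, meta, noise, log))
        cs_pd = condition_summary(events, meta)
        codes = _MetaCodes(design)
        cs_np = summary_frame(summaries_from_onsets(onsets, codes), codes.participants)
        merged = cs_pd.merge(cs_np, on=["participant", "condition"], suffixes=("_pd", "_np"))
        assert len(merged) == len(cs_pd)
        for col in ("mean_abs_async", "mean_sd_async", "z_lag_m1", "z_lag_0", "z_lag_p1"):
            np.testing.assert_allclose(merged[f"{col}_pd"], merged[f"{col}_np"], atol=1e-9)
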