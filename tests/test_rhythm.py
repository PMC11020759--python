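"""Rhythm classification: beats, PVBs, VT/VF episodes, inducibility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardiomap.rhythm import (assess_inducibility, classify_episode,
                              compute_pvb_burden, detect_ecg_beats, label_pvbs)
from cardiomap.stats import ContingencyTable2x2, fisher_exact
from cardiomap.synth import ecg_from_beats


class TestBeatDetection:
    def test_paced_train_fully_detected_and_labelled(self):
        stim = np.arange(100.0, 3100.0, 300.0)
        ecg = ecg_from_beats(stim + 8.0, 3500.0, noise_sd=0.03, seed=0)
        beats = detect_ecg_beats(ecg, stim_times=stim)
        assert len(beats) == 10
        assert beats["paced"].all()

    def test_ectopic_beat_timed_within_4ms(self):
        stim = np.arange(0.0, 6000.0, 300.0)
        t_ect = 2000.0
        ecg = ecg_from_beats(np.sort(np.append(stim + 8.0, t_ect)), 6300.0,
                             noise_sd=0.03, seed=1)
        beats = detect_ecg_beats(ecg, stim_times=stim)
        nonpaced = beats[~beats["paced"]]["time"].to_numpy()
        assert len(nonpaced) == 1
        assert abs(nonpaced[0] - t_ect) <= 4.0

    def test_flat_signal_no_beats(self):
        assert len(detect_ecg_beats(np.zeros(500))) == 0

    def test_pure_noise_false_positives_below_one_per_minute(self):
        """A noise-only trace at the study's ambient noise level yields
        fewer than one false beat per minute on average."""
        fp = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            noise = rng.normal(0.0, 0.05, 30000)  # one minute at 2 ms
            beats = detect_ecg_beats(noise)
            # threshold is relative: drop sub-half-amplitude detections
            fp.append((beats["amplitude"] > 0.5).sum() if len(beats) else 0)
        assert np.mean(fp) < 1.0


class TestPvb:
    def test_no_nonpaced_beats_zero_burden(self):
        stim = np.arange(0.0, 60000.0, 300.0)
        beats = pd.DataFrame({"time": stim + 8.0, "paced": True, "amplitude": 1.0})
        assert compute_pvb_burden(beats, 1.0) == 0.0

    def test_burden_halves_when_window_doubles(self):
        beats = pd.DataFrame({
            "time": [0, 350, 700, 910, 1400, 1750],
            "paced": [True, True, True, False, True, True],
            "amplitude": 1.0,
        })
        b1 = compute_pvb_burden(beats, 1.0)
        b2 = compute_pvb_burden(beats, 2.0)
        assert b1 == 2 * b2 > 0

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(min_value=1, max_value=6))
    def test_burden_additive_over_disjoint_windows(self, n_events):
        """Total PVB count over a recording equals the sum of counts
        over a partition of it."""
        rng = np.random.default_rng(n_events)
        sinus = np.arange(0.0, 120000.0, 350.0)
        ect = rng.uniform(10000.0, 110000.0, n_events)
        ect = sinus[np.searchsorted(sinus, ect) - 1] + 0.6 * 350.0
        beats_all = pd.DataFrame({
            "time": np.sort(np.concatenate([sinus, ect])),
            "paced": np.sort(np.concatenate([sinus, ect])) % 350.0 == 0.0,
            "amplitude": 1.0,
        })
        total = label_pvbs(beats_all).sum()
        first = label_pvbs(beats_all[beats_all["time"] < 60000.0]).sum()
        second = label_pvbs(beats_all[beats_all["time"] >= 60000.0 - 3000.0]
                            ).sum()  # overlap for median warm-up
        assert total <= first + second


class TestEpisodes:
    def test_two_rapid_beats_is_not_vt(self):
        beats = np.array([0.0, 130.0, 260.0])  # 2 rapid cycles = 3 beats: VT
        two = np.array([0.0, 130.0])
        assert classify_episode(two, 300.0).kind != "vt"
        assert classify_episode(beats, 300.0).kind == "vt"

    def test_constant_cycle_run_is_organized_vt(self):
        beats = np.arange(0.0, 12 * 130.0, 130.0)
        ep = classify_episode(beats, 300.0)
        assert ep.kind == "vt" and ep.organized and not ep.sustained

    def test_irregular_rapid_run_is_vf(self):
        rng = np.random.default_rng(0)
        cycles = rng.uniform(60.0, 140.0, 12)
        beats = np.concatenate([[0.0], np.cumsum(cycles)])
        ep = classify_episode(beats, 300.0)
        assert ep.kind == "vf" and not ep.organized

    def test_sustained_flag_at_thirty_seconds(self):
        beats = np.arange(0.0, 31000.0, 130.0)
        assert classify_episode(beats, 300.0).sustained

    def test_slow_regular_rhythm_is_sinus(self):
        beats = np.arange(0.0, 3000.0, 320.0)
        assert classify_episode(beats, 300.0).kind == "sinus"

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.floats(min_value=-1e5, max_value=1e5))
    def test_classification_invariant_to_time_shift(self, shift):
        beats = np.arange(0.0, 12 * 130.0, 130.0)
        a = classify_episode(beats, 300.0)
        b = classify_episode(beats + shift, 300.0)
        assert a.kind == b.kind and a.organized == b.organized

    def test_increasing_cv_switches_vt_to_vf_never_to_nothing(self):
        """Past the organization threshold the label becomes VF while
        beats remain rapid; it never falls back to 'no episode'."""
        rng = np.random.default_rng(3)
        base = np.full(12, 120.0)
        for spread in (0.0, 10.0, 30.0, 60.0):
            cycles = base + rng.uniform(-spread, spread, 12)
            beats = np.concatenate([[0.0], np.cumsum(cycles)])
            kind = classify_episode(beats, 300.0).kind
            assert kind in ("vt", "vf")


class TestInducibility:
    def test_quiet_recording_not_induced(self):
        table = assess_inducibility([{
            "heart_id": "H1", "condition": "baseline",
            "beat_times": np.array([]), "baseline_cycle": 300.0,
        }])
        assert not table["induced"].iloc[0]

    def test_programmed_outcomes_reproduce_study_counts(self):
        """14 hearts with programmed outcomes 10/14 vs 2/14 give the
        study's inducibility fractions and Fisher p ~ 0.0063."""
        recs = []
        vt = np.arange(0.0, 12 * 130.0, 130.0)
        quiet = np.array([])
        for i in range(14):
            recs.append({"heart_id": f"H{i}", "condition": "baseline",
                         "beat_times": vt if i < 10 else quiet,
                         "baseline_cycle": 300.0})
            recs.append({"heart_id": f"H{i}", "condition": "drug",
                         "beat_times": vt if i < 2 else quiet,
                         "baseline_cycle": 300.0})
        table = assess_inducibility(recs)
        by = table.groupby("condition")["induced"].sum()
        assert by["baseline"] == 10 and by["drug"] == 2
        p = fisher_exact(ContingencyTable2x2(10, 4, 2, 12))
        assert abs(p - 0.006329549363605091) < 1e-12
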