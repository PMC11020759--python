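"""Feature extraction: activations, durations, tau fits, aggregation, ERP."""

import numpy as np
import pandas as pd
import pytest

from cardiomap.features import (aggregate_sites, beat_feature_table, capture_in_movie,
                                compute_duration, detect_activations, fit_ca_decay,
                                measure_erp_from_protocol)
from cardiomap.movie import InsufficientSitesError
from cardiomap.preprocess import build_quality_mask, preprocess
from cardiomap.synth import ap_waveform


def triangular_beat(rise_at=99.0, fall_ms=200.0, total_ms=600.0, dt=2.0):
    """Instant rise to 1 at ``rise_at``, linear fall to 0 over ``fall_ms``.

    The rise is placed between sample instants so the detector's
    midpoint convention for a one-frame upstroke is unbiased.
    """
    t = np.arange(0.0, total_ms, dt)
    tr = np.where((t >= rise_at) & (t < rise_at + fall_ms),
                  1.0 - (t - rise_at) / fall_ms, 0.0)
    return t, tr


class TestActivations:
    def test_single_analytic_beat_timing(self):
        """Steepest ascent of a known waveform located within 1 ms."""
        t = np.arange(0, 400, 2.0)
        tr = 1.0 / (1.0 + np.exp(-(t - 151.0) / 3.0))
        acts = detect_activations(tr, 2.0)
        assert len(acts) == 1
        assert abs(acts[0] - 151.0) <= 1.0

    def test_periodic_train_intervals(self):
        t = np.arange(0, 3200, 2.0)
        tr = np.zeros_like(t)
        for k in range(10):
            tr += ap_waveform(t - (60.0 + 300.0 * k), apd=120.0)
        acts = detect_activations(tr, 2.0)
        assert len(acts) == 10
        np.testing.assert_allclose(np.diff(acts), 300.0, atol=1.0)

    def test_flat_trace_empty_not_error(self):
        assert len(detect_activations(np.full(100, 0.3), 2.0)) == 0

    def test_simulated_movie_matches_truth_front(self, planar_sim):
        """Per-pixel detected activations track the clean-state front
        passage within 2 ms at 95% of sites."""
        from cardiomap.model import _upstroke_crossings

        sim = planar_sim
        pp = preprocess(sim.vm_movie, 1, 1)
        clean = sim.truth["clean_vm"]
        times = sim.truth["frame_times"]
        errs = []
        for c in range(10, 50, 2):
            truth = _upstroke_crossings(clean[:, 8, c], times)
            det = detect_activations(pp.data[:, 8, c], 2.0)
            if len(det) == len(truth):
                errs.extend(np.abs(det - truth))
        errs = np.asarray(errs)
        assert len(errs) > 50
        assert np.mean(errs <= 2.0) >= 0.95


class TestDuration:
    def test_triangular_apd80_is_160(self):
        t, tr = triangular_beat()
        acts = detect_activations(tr, 2.0)
        dur, ok = compute_duration(tr, acts[0], 0.8, 2.0)
        assert ok
        assert abs(dur - 160.0) <= 1.0

    @pytest.mark.parametrize("level,expected", [(1.0, 200.0), (0.5, 100.0),
                                                (0.2, 40.0)])
    def test_duration_scales_with_level(self, level, expected):
        t, tr = triangular_beat()
        acts = detect_activations(tr, 2.0)
        dur, ok = compute_duration(tr, acts[0], level, 2.0)
        assert ok
        assert abs(dur - expected) <= 1.5

    def test_monotone_in_level(self):
        t, tr = triangular_beat()
        acts = detect_activations(tr, 2.0)
        durs = [compute_duration(tr, acts[0], lv, 2.0)[0]
                for lv in (0.2, 0.4, 0.6, 0.8, 1.0)]
        assert np.all(np.diff(durs) > 0)

    def test_unrepolarized_beat_flagged_invalid(self):
        t = np.arange(0, 400, 2.0)
        tr = 1.0 / (1.0 + np.exp(-(t - 100.0) / 3.0))  # steps up, never returns
        acts = detect_activations(tr, 2.0)
        dur, ok = compute_duration(tr, acts[0], 0.8, 2.0)
        assert not ok and np.isnan(dur)


class TestTauFit:
    def _decay_trace(self, tau=50.0, dt=2.0, noise=0.0, seed=0, scale=1.0,
                     offset=0.0):
        t = np.arange(0, 600, dt)
        tr = np.zeros_like(t)
        rise = (t >= 100) & (t < 112)
        tr[rise] = (t[rise] - 100) / 12.0
        decay = t >= 112
        tr[decay] = np.exp(-(t[decay] - 112) / tau)
        if noise:
            tr = tr + np.random.default_rng(seed).normal(0, noise, tr.shape)
        return t, scale * tr + offset

    def test_exact_exponential_recovered(self):
        t, tr = self._decay_trace(tau=50.0)
        fit = fit_ca_decay(tr, 100.0, 2.0)
        assert fit.valid
        assert abs(fit.tau - 50.0) < 0.1

    def test_affine_invariance(self):
        t, tr = self._decay_trace(tau=50.0)
        f1 = fit_ca_decay(tr, 100.0, 2.0)
        f2 = fit_ca_decay(3.0 * tr + 0.2, 100.0, 2.0)
        assert abs(f1.tau - f2.tau) < 1e-6

    def test_monte_carlo_recovery_at_20db(self):
        """200 noise seeds at 20 dB SNR: mean tau within 2% of truth."""
        taus = []
        for seed in range(200):
            t, tr = self._decay_trace(tau=50.0, noise=0.1, seed=seed)
            fit = fit_ca_decay(tr, 100.0, 2.0)
            if fit.valid:
                taus.append(fit.tau)
        assert len(taus) > 190
        assert abs(np.mean(taus) - 50.0) / 50.0 < 0.02

    def test_flat_beat_invalid(self):
        fit = fit_ca_decay(np.full(200, 0.5), 100.0, 2.0)
        assert not fit.valid


class TestAggregation:
    def _table(self, values, beat_count=4):
        rows = []
        for i, v in enumerate(values):
            for b in range(beat_count):
                rows.append({"row": i // 10, "col": i % 10, "beat": b,
                             "activation_time": 100.0 * b, "duration": v,
                             "amplitude": 1.0, "di": 150.0, "paced": True,
                             "valid": True})
        return pd.DataFrame(rows)

    def test_identical_sites_zero_sd(self):
        agg = aggregate_sites(self._table([120.0] * 30))
        assert agg["mean"] == 120.0 and agg["sd"] == 0.0 and agg["n_sites"] == 30

    def test_twenty_four_sites_fail(self):
        with pytest.raises(InsufficientSitesError):
            aggregate_sites(self._table([120.0] * 24))

    def test_sampling_consistency(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(120.0, 5.0, 100)
        agg = aggregate_sites(self._table(list(vals)))
        assert abs(agg["mean"] - 120.0) < 1.5  # 3 standard errors
        assert 3.5 < agg["sd"] < 6.5


class TestErpFromProtocol:
    def test_longest_failing_interval(self):
        intervals = np.array([200.0, 190.0, 180.0, 170.0, 160.0])
        captured = np.array([True, True, False, False, False])
        assert measure_erp_from_protocol(intervals, captured) == 180.0

    def test_all_captured_raises(self):
        with pytest.raises(RuntimeError, match="below scan range"):
            measure_erp_from_protocol(np.array([200.0, 190.0]),
                                      np.array([True, True]))

    def test_capture_detection_on_movie(self, planar_sim):
        pp = preprocess(planar_sim.vm_movie, 1, 1)
        stim_times = planar_sim.truth["stim_times"]
        assert capture_in_movie(pp, (8, 2), stim_times[1])
        # no stimulus fired around t = halfway between beats
        assert not capture_in_movie(pp, (8, 2), stim_times[1] + 150.0, window_ms=100.0)
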