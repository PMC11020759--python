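"""Tissue simulator: determinism, wave speed, scar silence, capture,
refractory period, ectopy, and the pseudo-ECG operator."""

import numpy as np
import pytest

from cardiomap.geometry import TissueGeometry, with_scar
from cardiomap.model import (CellModelParams, PacingProtocol, SimulationError,
                             compute_pseudo_ecg, default_electrodes, inject_ectopy,
                             measure_true_erp, simulate_tissue, _upstroke_crossings)
from cardiomap.movie import OpticalMovie
from cardiomap.rhythm import detect_ecg_beats


class TestProtocol:
    def test_extrastimulus_times_are_cumulative(self):
        p = PacingProtocol(kind="extrastimulus", s1_count=3, s1s1=300.0,
                           extra_intervals=(200.0, 180.0), start_time=0.0)
        np.testing.assert_allclose(p.stimulus_times(), [0, 300, 600, 800, 980])

    def test_increasing_extras_rejected(self):
        with pytest.raises(ValueError):
            PacingProtocol(kind="extrastimulus", extra_intervals=(180.0, 200.0))

    def test_no_protocol_has_no_stimuli(self):
        assert len(PacingProtocol(kind="none").stimulus_times()) == 0


class TestSimulation:
    def test_no_stimulus_no_noise_is_flat(self):
        geo = TissueGeometry(16, 20)
        sim = simulate_tissue(geo, CellModelParams(), PacingProtocol(kind="none"),
                              noise_snr_db=np.inf, seed=0, record_tail_ms=100.0)
        assert float(sim.vm_movie.data.std()) == 0.0
        assert float(sim.cai_movie.data.std()) < 1e-12

    def test_same_seed_bit_identical(self):
        geo = TissueGeometry(16, 20)
        proto = PacingProtocol(kind="burst", s1_count=2, s1s1=250.0, stim_site=(8, 2))
        a = simulate_tissue(geo, CellModelParams(), proto, noise_snr_db=20.0, seed=5)
        b = simulate_tissue(geo, CellModelParams(), proto, noise_snr_db=20.0, seed=5)
        np.testing.assert_array_equal(a.vm_movie.data, b.vm_movie.data)
        np.testing.assert_array_equal(a.cai_movie.data, b.cai_movie.data)
        np.testing.assert_array_equal(a.pseudo_ecg, b.pseudo_ecg)
        assert a.stimulus_log == b.stimulus_log

    def test_different_seed_changes_noise_only(self):
        geo = TissueGeometry(16, 20)
        proto = PacingProtocol(kind="burst", s1_count=2, s1s1=250.0, stim_site=(8, 2))
        a = simulate_tissue(geo, CellModelParams(), proto, noise_snr_db=20.0, seed=5)
        b = simulate_tissue(geo, CellModelParams(), proto, noise_snr_db=20.0, seed=6)
        assert not np.array_equal(a.vm_movie.data, b.vm_movie.data)
        np.testing.assert_array_equal(a.truth["clean_vm"], b.truth["clean_vm"])

    def test_first_beat_speed_matches_closed_form(self, fine_strip_sim):
        """Front-tracked speed of the first wavefront from rest vs the
        analytic cubic-front formula, within 5%."""
        sim = fine_strip_sim
        clean = sim.truth["clean_vm"]
        times = sim.truth["frame_times"]
        pitch = sim.vm_movie.pixel_pitch
        cols = np.arange(32, 136)
        acts = [_upstroke_crossings(clean[:, 8, c], times)[0] for c in cols]
        slope = np.polyfit(cols * pitch, acts, 1)[0]  # ms/mm
        c_formula = CellModelParams().plane_wave_speed()
        assert abs(1.0 / slope - c_formula) / c_formula < 0.05

    def test_scar_pixels_carry_no_wave_signal(self, scar_sim):
        """Scar-pixel traces are uncorrelated with the pacing train."""
        geo, sim = scar_sim
        clean = sim.truth["clean_vm"]
        assert float(np.abs(clean[:, geo.scar_mask]).max()) == 0.0
        # in the noisy recording, scar traces are baseline plus noise of
        # exactly the configured SD, uncorrelated with the paced signal
        scar_trace = sim.vm_movie.data[:, geo.scar_mask]
        sigma = 0.8 / 10.0 ** (20.0 / 20.0)
        assert abs(scar_trace.std() - sigma) < 0.2 * sigma
        tissue_mean = sim.vm_movie.data[:, ~geo.scar_mask].mean(axis=1)
        scar_mean = scar_trace.mean(axis=1)
        corr = np.corrcoef(tissue_mean, scar_mean)[0, 1]
        assert abs(corr) < 0.1

    def test_conservation_of_beats(self, planar_sim):
        """Captured stimuli equal wavefronts crossing a distal line."""
        sim = planar_sim
        n_captured = sum(cap for _, _, cap in sim.stimulus_log)
        clean = sim.truth["clean_vm"]
        times = sim.truth["frame_times"]
        crossings = _upstroke_crossings(clean[:, 8, 50], times)
        assert len(crossings) == n_captured

    def test_stimulus_in_scar_rejected(self):
        geo = with_scar(24, 24, scar_center=(12.0, 12.0), scar_radius_px=4.0)
        proto = PacingProtocol(kind="burst", s1_count=1, stim_site=(12, 12))
        with pytest.raises(ValueError, match="scar"):
            simulate_tissue(geo, CellModelParams(), proto)


class TestPseudoEcg:
    def test_uniform_field_gives_zero_trace(self):
        movie = OpticalMovie(np.full((10, 16, 16), 0.7), pixel_pitch=0.25)
        geo = TissueGeometry(16, 16)
        ecg = compute_pseudo_ecg(movie, default_electrodes(geo))
        np.testing.assert_allclose(ecg, 0.0, atol=1e-12)

    def test_linearity(self, planar_sim):
        movie = OpticalMovie(planar_sim.truth["clean_vm"].astype(float))
        geo = TissueGeometry(16, 60)
        el = default_electrodes(geo)
        e1 = compute_pseudo_ecg(movie, el)
        e2 = compute_pseudo_ecg(movie.with_data(2.0 * movie.data), el)
        np.testing.assert_allclose(e2, 2.0 * e1, rtol=1e-9, atol=1e-12)

    def test_one_deflection_per_paced_beat(self, planar_sim):
        beats = detect_ecg_beats(planar_sim.pseudo_ecg,
                                 stim_times=planar_sim.truth["stim_times"],
                                 refractory_ms=150.0)
        n_captured = sum(cap for _, _, cap in planar_sim.stimulus_log)
        assert len(beats) == n_captured
        assert beats["paced"].all()

    def test_electrode_on_pixel_rejected(self):
        movie = OpticalMovie(np.zeros((4, 16, 16)) + np.arange(4)[:, None, None])
        with pytest.raises(ValueError, match="singular"):
            compute_pseudo_ecg(movie, [(1.0, 1.0, 0.0), (5.0, 5.0, 5.0)])


class TestErp:
    @pytest.fixture(scope="class")
    def strip(self):
        return TissueGeometry(16, 32)

    def test_drug_prolongs_erp(self, strip):
        base = measure_true_erp(strip, CellModelParams(), s2_start=200.0, s2_step=4.0,
                                s1_count=3, stim_site=(8, 2), stim_amplitude=1.6,
                                strategy="bisect")
        drug = measure_true_erp(strip, CellModelParams(drug_apd_factor=1.10),
                                s2_start=220.0, s2_step=4.0, s1_count=3,
                                stim_site=(8, 2), stim_amplitude=1.6,
                                strategy="bisect")
        assert drug > base

    def test_bisect_agrees_with_descend(self, strip):
        kw = dict(s2_start=200.0, s2_step=4.0, s1_count=3, stim_site=(8, 2),
                  stim_amplitude=1.6)
        a = measure_true_erp(strip, CellModelParams(), strategy="descend", **kw)
        b = measure_true_erp(strip, CellModelParams(), strategy="bisect", **kw)
        assert a == b

    def test_scan_start_below_erp_fails(self, strip):
        with pytest.raises(SimulationError, match="did not capture"):
            measure_true_erp(strip, CellModelParams(), s2_start=100.0, s2_step=4.0,
                             s1_count=3, stim_site=(8, 2), stim_amplitude=1.6)


class TestEctopy:
    @pytest.fixture(scope="class")
    def geo(self):
        return with_scar(32, 32, scar_center=(16.0, 16.0), scar_radius_px=5.0)

    def test_zero_rate_no_events(self, geo):
        origin = tuple(np.argwhere(geo.border_zone_mask)[0])
        ev = inject_ectopy(geo, CellModelParams(), 0.0, origin, 60000.0, seed=0)
        assert len(ev.delivered) == 0

    def test_rate_recovery_within_ten_percent(self, geo):
        """Mean delivered rate over many seeds recovers the nominal
        0.55/min burden within 10% (refractory losses are tiny)."""
        origin = tuple(np.argwhere(geo.border_zone_mask)[0])
        rates = []
        for seed in range(200):
            ev = inject_ectopy(geo, CellModelParams(), 0.55, origin, 20 * 60000.0,
                               seed=seed)
            rates.append(len(ev.delivered) / 20.0)
        assert abs(np.mean(rates) - 0.55) / 0.55 < 0.10

    def test_refractory_suppression_can_silence(self, geo):
        """With paced beats saturating the refractory period, every
        candidate is suppressed despite a positive rate."""
        origin = tuple(np.argwhere(geo.border_zone_mask)[0])
        paced = np.arange(0.0, 60000.0, 50.0)  # far denser than refractoriness
        ev = inject_ectopy(geo, CellModelParams(), 2.0, origin, 60000.0, seed=1,
                           paced_times=paced, refractory_ms=200.0)
        assert len(ev.delivered) == 0
        assert len(ev.suppressed) > 0

    def test_origin_in_scar_rejected(self, geo):
        with pytest.raises(ValueError, match="scar"):
            inject_ectopy(geo, CellModelParams(), 1.0, (16, 16), 1000.0, seed=0)
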