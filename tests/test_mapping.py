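"""Isochrones, conduction velocity, block lines, phase, singularities."""

import numpy as np
import pandas as pd
import pytest

from cardiomap.mapping import (IsochroneMap, build_isochrone, compute_phase,
                               detect_conduction_block, detect_singularities,
                               estimate_cv, isochrone_from_array,
                               singularity_charge_map)
from cardiomap.movie import OpticalMovie
from cardiomap.synth import spiral_phase_movie


def planar_iso(speed=0.4, shape=(20, 30), pitch=0.25, angle=0.0):
    """Analytic planar isochrones: T = (x cos a + y sin a) / c."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    T = (xx * np.cos(angle) + yy * np.sin(angle)) * pitch / speed
    return isochrone_from_array(T, pitch)


class TestIsochrone:
    def test_single_site_map(self):
        feats = pd.DataFrame([{"row": 3, "col": 4, "beat": 0,
                               "activation_time": 120.0, "duration": 100.0,
                               "amplitude": 1.0, "di": np.nan, "paced": True,
                               "valid": True}])
        iso = build_isochrone(feats, 0, (8, 8))
        assert iso.activation_time[3, 4] == 0.0
        assert iso.unactivated.sum() == 63

    def test_reference_is_earliest_activation(self):
        rows = [{"row": 0, "col": c, "beat": 0, "activation_time": 100.0 + 5 * c,
                 "duration": 100.0, "amplitude": 1.0, "di": np.nan,
                 "paced": True, "valid": True} for c in range(5)]
        iso = build_isochrone(pd.DataFrame(rows), 0, (1, 5))
        assert iso.reference_time == 100.0
        np.testing.assert_allclose(iso.activation_time[0], [0, 5, 10, 15, 20])


class TestConductionVelocity:
    def test_analytic_planar_speed_within_one_percent(self):
        est = estimate_cv(planar_iso(speed=0.4))
        assert abs(est["median_speed"] - 0.4) / 0.4 < 0.01

    def test_rotation_equivariance(self):
        a = estimate_cv(planar_iso(speed=0.4, shape=(24, 24), angle=0.0))
        b = estimate_cv(planar_iso(speed=0.4, shape=(24, 24), angle=np.pi / 2))
        assert abs(a["median_speed"] - b["median_speed"]) < 1e-9
        # velocity directions rotate with the wave
        ok_a = np.isfinite(a["vx"])
        assert np.nanmedian(np.abs(a["vx"][ok_a])) > np.nanmedian(np.abs(a["vy"][ok_a]))

    def test_circular_wave_velocities_are_radial(self):
        yy, xx = np.mgrid[0:30, 0:30]
        r = np.sqrt((yy - 15.0) ** 2 + (xx - 15.0) ** 2) * 0.25
        iso = isochrone_from_array(r / 0.4, 0.25)
        est = estimate_cv(iso)
        angles = []
        for row in range(30):
            for col in range(30):
                rad = np.sqrt((row - 15.0) ** 2 + (col - 15.0) ** 2)
                if rad <= 5 or not np.isfinite(est["speed"][row, col]):
                    continue
                v = np.array([est["vy"][row, col], est["vx"][row, col]])
                rhat = np.array([row - 15.0, col - 15.0]) / rad
                cosang = np.dot(v, rhat) / np.linalg.norm(v)
                angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        assert np.percentile(angles, 95) < 5.0

    def test_simulated_planar_wave_within_five_percent(self, fine_strip_sim):
        """Estimator on the simulated first wavefront agrees with an
        independent front-tracking oracle within 5%."""
        from cardiomap.model import _upstroke_crossings

        sim = fine_strip_sim
        clean = sim.truth["clean_vm"]
        times = sim.truth["frame_times"]
        pitch = sim.vm_movie.pixel_pitch
        act = np.full(clean.shape[1:], np.nan)
        for r in range(4, 12):
            for c in range(32, 136):
                ups = _upstroke_crossings(clean[:, r, c], times)
                if len(ups):
                    act[r, c] = ups[0]
        iso = isochrone_from_array(act, pitch)
        est = estimate_cv(iso)
        # oracle: global linear front fit along the propagation axis
        cols = np.arange(32, 136)
        slope = np.polyfit(cols * pitch, act[8, 32:136], 1)[0]
        oracle = 1.0 / slope
        assert abs(est["median_speed"] - oracle) / oracle < 0.05


class TestBlock:
    def test_planar_wave_has_no_block(self):
        blk = detect_conduction_block(planar_iso(), grad_threshold=4.0)
        assert not blk["block"].any()

    def test_steep_jump_detected_as_block(self):
        T = np.zeros((10, 20))
        T[:, 10:] = 50.0  # 50 ms jump across one pixel
        blk = detect_conduction_block(isochrone_from_array(T), grad_threshold=4.0)
        cols = np.unique(np.nonzero(blk["block"])[1])
        np.testing.assert_array_equal(cols, [9, 10])

    def test_scar_adjacent_block_labelled_fixed(self):
        """The same steep activation-time line is 'fixed' where it runs
        against the scar and 'functional' where it crosses free wall."""
        T = np.zeros((16, 12))
        T[:, 6:] = 60.0  # block line between cols 5 and 6, full height
        scar = np.zeros((16, 12), dtype=bool)
        scar[0:5, 4:6] = True  # infarct hugging the upper part of the line
        T[scar] = np.nan
        blk = detect_conduction_block(isochrone_from_array(T), grad_threshold=10.0,
                                      scar_mask=scar)
        fixed_rows = np.unique(np.nonzero(blk["fixed"])[0])
        func_rows = np.unique(np.nonzero(blk["functional"])[0])
        assert blk["fixed"].any() and blk["functional"].any()
        assert fixed_rows.max() <= 7   # near the scar (2-px dilation)
        assert func_rows.min() >= 5    # away from it


class TestPhase:
    def test_sinusoid_sweeps_two_pi_per_period(self):
        t = np.arange(0, 2000, 2.0)
        data = np.tile(np.sin(2 * np.pi * t / 200.0)[:, None, None], (1, 4, 4))
        movie = OpticalMovie(data + 0.5)
        pm = compute_phase(movie)
        phase = np.unwrap(pm.phase[:, 2, 2])
        inner = slice(100, 900)
        rate = np.diff(phase[inner]) / 2.0
        expected = 2 * np.pi / 200.0
        assert np.max(np.abs(rate - expected)) < 0.1 * expected

    def test_constant_pixel_invalidated(self):
        t = np.arange(0, 400, 2.0)
        data = np.tile(np.sin(2 * np.pi * t / 100.0)[:, None, None], (1, 4, 4))
        data[:, 1, 1] = 0.3
        pm = compute_phase(OpticalMovie(data))
        assert not pm.valid[1, 1]
        assert np.all(np.isnan(pm.phase[:, 1, 1]))

    def test_window_too_short_fails(self):
        with pytest.raises(ValueError):
            compute_phase(OpticalMovie(np.random.default_rng(0).normal(size=(4, 4, 4))))


class TestSingularities:
    def test_spiral_has_exactly_one_of_given_chirality(self):
        phase = spiral_phase_movie(chirality=1)
        from cardiomap.mapping import PhaseMovie

        tracks = detect_singularities(PhaseMovie(phase, 2.0))
        assert len(tracks) == 1
        assert tracks[0].chirality == 1
        r, c = tracks[0].positions.mean(axis=0)
        assert abs(r - 19.5) <= 1.0 and abs(c - 19.5) <= 1.0

    def test_mirrored_spiral_flips_chirality(self):
        from cardiomap.mapping import PhaseMovie

        phase = spiral_phase_movie(chirality=-1)
        tracks = detect_singularities(PhaseMovie(phase, 2.0))
        assert len(tracks) == 1
        assert tracks[0].chirality == -1

    def test_planar_phase_has_no_singularity(self):
        yy, xx = np.mgrid[0:30, 0:30]
        frames = np.stack([(0.3 * xx - 0.1 * k + np.pi) % (2 * np.pi) - np.pi
                           for k in range(10)])
        from cardiomap.mapping import PhaseMovie

        assert detect_singularities(PhaseMovie(frames, 2.0)) == []

    def test_figure_eight_pair_of_opposite_chirality(self):
        """Two counter-rotating spirals yield two tracks of opposite
        chirality (figure-of-eight reentry)."""
        h0, w0 = 40, 60
        rr, cc = np.mgrid[0:h0, 0:w0]
        base = (np.arctan2(rr - 19.5, cc - 14.5)
                - np.arctan2(rr - 19.5, cc - 44.5))
        frames = np.stack([(base - 0.3 * k + np.pi) % (2 * np.pi) - np.pi
                           for k in range(12)])
        from cardiomap.mapping import PhaseMovie

        tracks = detect_singularities(PhaseMovie(frames, 2.0))
        assert len(tracks) == 2
        assert sorted(t.chirality for t in tracks) == [-1, 1]

    def test_total_charge_conserved_per_frame(self):
        """Net plaquette charge equals the boundary winding on every
        frame of a synthetic spiral field."""
        phase = spiral_phase_movie(chirality=1, n_frames=8)
        for frame in phase:
            assert singularity_charge_map(frame).sum() == 1.0

    def test_charge_invariant_to_global_offset_and_rotation(self):
        frame = spiral_phase_movie(n_frames=1)[0]
        base = singularity_charge_map(frame).sum()
        shifted = (frame + 1.234 + np.pi) % (2 * np.pi) - np.pi
        assert singularity_charge_map(shifted).sum() == base
        assert singularity_charge_map(np.rot90(frame)).sum() == base
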