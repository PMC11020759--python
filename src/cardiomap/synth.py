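"""Schedule-driven synthesis of optical movies and pseudo-ECG traces.

The reaction-diffusion simulator is the high-fidelity source of
recordings, but many pipeline stages only need movies with *known*
activation times, durations, and amplitudes per site and beat.  This
module renders such beat schedules into fluorescence movies using
analytic waveforms whose APD80 is exact by construction, and renders
beat-time lists into far-field-like ECG traces.  Combined with the
restitution cable it yields, in milliseconds of compute, recordings of
spatially discordant alternans with a ground-truth nodal line, paced
trains with ectopic beats, and VT/VF-like post-pacing episodes.
"""

from __future__ import annotations

import numpy as np

from .movie import OpticalMovie
from .restitution import RestitutionMap, run_restitution_cable


def ap_waveform(t: np.ndarray, apd: float, upstroke_ms: float = 2.0,
                level: float = 0.8) -> np.ndarray:
    """Action-potential shape with an exact duration at ``level``.

    Rapid linear upstroke over ``upstroke_ms`` then exponential
    repolarization with rate set so the waveform crosses
    ``1 - level`` (i.e. 80% repolarization for level 0.8) exactly at
    ``t = apd``.  Zero before activation and effectively zero well
    after repolarization.
    """
    t = np.asarray(t, dtype=float)
    k = np.log(1.0 / (1.0 - level)) / max(apd, 1e-6)
    up = np.clip(t / upstroke_ms, 0.0, 1.0)
    rep = np.exp(-k * np.clip(t, 0.0, None))
    return np.where(t < 0, 0.0, up * rep)


def ca_waveform(t: np.ndarray, tau_decay: float, rise_ms: float = 12.0) -> np.ndarray:
    """Calcium-transient shape: smooth rise, exact monoexponential decay."""
    t = np.asarray(t, dtype=float)
    rise = 1.0 - np.exp(-np.clip(t, 0.0, None) / (rise_ms / 3.0))
    decay = np.exp(-np.clip(t - rise_ms, 0.0, None) / tau_decay)
    return np.where(t < 0, 0.0, rise * decay)


def movie_from_schedule(
    activation_times: np.ndarray,
    apds: np.ndarray,
    amplitudes: np.ndarray | None = None,
    grid_shape: tuple[int, int] | None = None,
    duration_ms: float | None = None,
    frame_interval: float = 2.0,
    pixel_pitch: float = 0.25,
    channel: str = "vm",
    tau_ca: float = 50.0,
    noise_snr_db: float = np.inf,
    seed: int = 0,
    baseline: float = 0.1,
    gain: float = 0.8,
) -> OpticalMovie:
    """Render a (site, beat) activation/duration schedule into a movie.

    ``activation_times`` and ``apds`` are (n_sites, n_beats) arrays (NaN
    = dropped beat); sites fill the grid row-major.  The voltage channel
    uses :func:`ap_waveform` (upright polarity: synthetic movies are
    emitted already-conditioned), the calcium channel
    :func:`ca_waveform` scaled by per-beat amplitudes.
    """
    activation_times = np.atleast_2d(np.asarray(activation_times, dtype=float))
    apds = np.atleast_2d(np.asarray(apds, dtype=float))
    if activation_times.shape != apds.shape:
        raise ValueError("activation_times and apds shapes differ")
    n_sites, n_beats = activation_times.shape
    if amplitudes is None:
        amplitudes = np.ones_like(apds)
    amplitudes = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    if grid_shape is None:
        grid_shape = (1, n_sites)
    if grid_shape[0] * grid_shape[1] != n_sites:
        raise ValueError("grid_shape does not hold n_sites")
    if duration_ms is None:
        duration_ms = np.nanmax(activation_times) + np.nanmax(apds) + 200.0
    n_frames = int(round(duration_ms / frame_interval)) + 1
    times = np.arange(n_frames) * frame_interval

    traces = np.zeros((n_sites, n_frames))
    for s in range(n_sites):
        for b in range(n_beats):
            t_act, apd = activation_times[s, b], apds[s, b]
            if not (np.isfinite(t_act) and np.isfinite(apd)):
                continue
            rel = times - t_act
            if channel == "vm":
                w = ap_waveform(rel, apd)
            else:
                w = ca_waveform(rel, tau_ca) * amplitudes[s, b]
            traces[s] = np.maximum(traces[s], w)
    data = baseline + gain * traces.T.reshape(n_frames, *grid_shape)
    if np.isfinite(noise_snr_db):
        rng = np.random.default_rng(seed)
        sigma = gain / 10.0 ** (noise_snr_db / 20.0)
        data = data + rng.normal(0.0, sigma, data.shape)
    return OpticalMovie(data, frame_interval, pixel_pitch, channel, "upright",
                        {"synthetic_schedule": True, "seed": seed})


def ecg_from_beats(
    beat_times: np.ndarray,
    duration_ms: float,
    sample_interval: float = 2.0,
    amplitudes: np.ndarray | None = None,
    width_ms: float = 18.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render beat times into a biphasic-deflection ECG-like trace.

    Each beat contributes a Gaussian-derivative wavelet (one biphasic
    deflection), the far-field signature of a propagating wavefront.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    n = int(round(duration_ms / sample_interval)) + 1
    t = np.arange(n) * sample_interval
    if amplitudes is None:
        amplitudes = np.ones(len(beat_times))
    ecg = np.zeros(n)
    half = int(np.ceil(5.0 * width_ms / sample_interval))  # wavelet support
    for tb, a in zip(beat_times, np.asarray(amplitudes, dtype=float)):
        i0 = max(0, int(tb / sample_interval) - half)
        i1 = min(n, int(tb / sample_interval) + half + 1)
        rel = (t[i0:i1] - tb) / width_ms
        ecg[i0:i1] += -a * rel * np.exp(-0.5 * rel * rel)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ecg = ecg + rng.normal(0.0, noise_sd, n)
    return ecg


def discordant_alternans_recording(
    rmap: RestitutionMap | None = None,
    pcl: float = 130.0,
    n_sites: int = 50,
    n_beats: int = 150,
    strip_height: int = 8,
    record_beats: int = 8,
    noise_snr_db: float = np.inf,
    seed: int = 0,
    premature_fraction: float | None = None,
):
    """Cable run with CV restitution rendered as a 2D strip movie.

    Returns ``(vm_movie, features_truth)`` where the truth dict holds
    the per-site steady-state signed alternation profile, the true
    nodal position (zero crossing of that profile, in columns), and the
    beat schedule.  Requires parameters that actually produce
    discordance; raises if the steady state is concordant.

    With ``premature_fraction`` set (e.g. 0.8), one extra stimulus is
    delivered that fraction of a cycle after the last paced beat; on a
    discordant substrate it conducts through the short-APD region and
    blocks near the nodal line.  The truth then also carries
    ``block_site`` (first blocked column) and ``premature_beat``.
    """
    if rmap is None:
        # gentle CV restitution with a long time constant puts a single
        # node in mid-cable (stronger/faster CV restitution shortens the
        # discordance wavelength and packs in several nodes)
        rmap = RestitutionMap(apd_max=130.0, amplitude_a=120.0, tau_restitution=40.0,
                              cv_max=0.35, cv_amplitude=0.15, cv_tau=100.0, di_min=2.0)
    stim_times = np.arange(n_beats) * float(pcl)
    if premature_fraction is not None:
        stim_times = np.append(stim_times, stim_times[-1] + premature_fraction * pcl)
    res = run_restitution_cable(rmap, pcl, n_beats, n_sites=n_sites,
                                stim_times=stim_times)
    last_regular = n_beats - 1
    steady = res[(res["beat"] >= n_beats - record_beats) & (res["beat"] <= last_regular)]
    # signed alternation profile over the recorded window
    profile = np.full(n_sites, np.nan)
    for s in range(n_sites):
        apd = steady[steady["site"] == s].sort_values("beat")["apd"].to_numpy()
        if np.all(np.isfinite(apd)) and len(apd) >= 4:
            vals = apd[: len(apd) - len(apd) % 2]
            profile[s] = np.mean(vals[0::2] - vals[1::2])
    signs = np.sign(profile[np.isfinite(profile)])
    if not ((signs > 0).any() and (signs < 0).any()):
        raise ValueError("cable steady state is not discordant at this PCL")
    # true node: zero crossing of the profile, linear interpolation
    # (skip the first few sites: the paced end has its own boundary phase)
    node = None
    for s in range(3, n_sites - 1):
        if np.isfinite(profile[s]) and np.isfinite(profile[s + 1]) and \
                profile[s] * profile[s + 1] < 0:
            frac = abs(profile[s]) / (abs(profile[s]) + abs(profile[s + 1]))
            node = s + frac
            break
    recorded = res[res["beat"] >= n_beats - record_beats]
    n_rec_beats = recorded["beat"].nunique()
    acts = np.full((strip_height * n_sites, n_rec_beats), np.nan)
    durs = np.full_like(acts, np.nan)
    t0 = recorded["activation_time"].min()
    for s in range(n_sites):
        sub = recorded[recorded["site"] == s].sort_values("beat")
        a = sub["activation_time"].to_numpy() - t0 + 50.0
        d = sub["apd"].to_numpy()
        nb = min(n_rec_beats, len(a))
        for row in range(strip_height):
            acts[row * n_sites + s, :nb] = a[:nb]
            durs[row * n_sites + s, :nb] = d[:nb]
    vm = movie_from_schedule(acts, durs, grid_shape=(strip_height, n_sites),
                             noise_snr_db=noise_snr_db, seed=seed)
    truth = {
        "profile": profile,
        "node_col": node,
        "cable": res,
        "pcl": pcl,
        "first_recorded_beat": n_beats - record_beats,
        "schedule_t0": float(t0 - 50.0),
    }
    if premature_fraction is not None:
        prem = res[res["beat"] == n_beats].sort_values("site")
        cap = prem["captured"].to_numpy()
        truth["premature_beat"] = int(n_beats)
        truth["block_site"] = int(np.argmin(cap)) if (~cap).any() and cap.any() else None
    return vm, truth


def spiral_phase_movie(
    shape: tuple[int, int] = (40, 40),
    center: tuple[float, float] | None = None,
    n_frames: int = 20,
    period_frames: int = 10,
    chirality: int = 1,
) -> np.ndarray:
    """Analytic rotating-spiral phase stack phi = chi*atan2(dy, dx) - w t.

    A rigidly rotating phase field with exactly one singularity of the
    given chirality at ``center``; useful as a closed-form oracle for
    the singularity detector.
    """
    h0, w0 = shape
    if center is None:
        center = ((h0 - 1) / 2.0, (w0 - 1) / 2.0)
    rr, cc = np.mgrid[0:h0, 0:w0]
    base = np.arctan2(rr - center[0], cc - center[1]) * chirality
    omega = 2.0 * np.pi / period_frames
    frames = [(base - omega * k + np.pi) % (2 * np.pi) - np.pi for k in range(n_frames)]
    return np.stack(frames)
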