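"""Two-variable excitable-tissue simulator with a driven calcium subsystem.

The membrane model is of the Mitchell-Schaeffer family: a fast
activation variable ``v`` and a slow recovery gate ``h``,

    dv/dt = h * v^2 * (1 - v) / tau_in  -  v / tau_out  +  I_stim  +  D lap(v)
    dh/dt = (1 - h) / tau_open   if v <  v_gate
          = -h / tau_close       if v >= v_gate

chosen because its action-potential-duration restitution and plane-wave
speed are analytically tractable, so simulator ground truth can be
cross-checked in closed form.  Intracellular calcium is a driven
relaxation,

    dCa/dt = gain * s(v) - Ca / tau_ca,

with ``s`` a smooth upstroke-gated source, so the diastolic Ca decay is
exactly monoexponential with the configured time constant.

Space is a regular grid (camera pixels) with a 5-point Laplacian,
no-flux boundaries, and scar cells removed from the medium entirely
(internal no-flux boundaries; their optical output is noise only).
Integration is forward Euler at an internal step well below the
diffusion stability limit; output is resampled to the camera's 2 ms
frames.  A "drug" is represented purely parametrically: a multiplier
>1 on tau_close prolongs APD and refractoriness, a multiplier <1 on
tau_ca accelerates calcium reuptake.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import TissueGeometry
from .movie import OpticalMovie


class SimulationError(RuntimeError):
    pass


class UnstableIntegrationError(SimulationError):
    """Non-finite state encountered; message names the offending time."""


# ---------------------------------------------------------------------------
# parameters and protocol


@dataclass
class CellModelParams:
    """Cell and tissue parameters (times in ms, D in mm^2/ms).

    ``drug_apd_factor`` multiplies ``tau_close`` (>1 prolongs APD and
    the effective refractory period); ``drug_ca_factor`` multiplies
    ``tau_ca_decay`` (<1 accelerates calcium decay).
    """

    tau_in: float = 0.3
    tau_out: float = 6.0
    tau_open: float = 120.0
    tau_close: float = 70.0
    v_gate: float = 0.13
    diffusion_coeff: float = 0.1
    ca_amplitude_gain: float = 1.0
    tau_ca_decay: float = 50.0
    drug_apd_factor: float = 1.0
    drug_ca_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tau_in", "tau_out", "tau_open", "tau_close",
                     "tau_ca_decay", "diffusion_coeff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.drug_apd_factor <= 0 or self.drug_ca_factor <= 0:
            raise ValueError("drug factors must be positive")
        if not (0 < self.v_gate < 1):
            raise ValueError("v_gate must be in (0, 1)")

    @property
    def tau_close_eff(self) -> float:
        return self.tau_close * self.drug_apd_factor

    @property
    def tau_ca_eff(self) -> float:
        return self.tau_ca_decay * self.drug_ca_factor

    @property
    def h_min(self) -> float:
        """Minimum gate value that still sustains an action potential."""
        return 4.0 * self.tau_in / self.tau_out

    def resting_excitation_thresholds(self) -> tuple[float, float]:
        """Roots (v-, v+) of the resting cubic nullcline (h = 1)."""
        c = self.tau_in / self.tau_out
        disc = math.sqrt(1.0 - 4.0 * c)
        return (1.0 - disc) / 2.0, (1.0 + disc) / 2.0

    def plane_wave_speed(self) -> float:
        """Closed-form continuum plane-wave speed, mm/ms.

        The upstroke (h ~ 1) reduces the v-equation to a cubic bistable
        reaction-diffusion front with roots 0 < v- < v+, whose speed is
        sqrt(D / (2 tau_in)) * (v+ - 2 v-).
        """
        vm, vp = self.resting_excitation_thresholds()
        return math.sqrt(self.diffusion_coeff / (2.0 * self.tau_in)) * (vp - 2.0 * vm)

    def apd_restitution(self, di: float) -> float:
        """Analytic single-cell APD after a diastolic interval ``di``."""
        h0 = 1.0 - (1.0 - self.h_min) * math.exp(-di / self.tau_open)
        if h0 <= self.h_min:
            return 0.0
        return self.tau_close_eff * math.log(h0 / self.h_min)


@dataclass
class PacingProtocol:
    """Stimulation schedule.

    ``extrastimulus``: ``s1_count`` beats at ``s1s1`` followed by premature
    extras at the cumulative ``extra_intervals`` (S2, S3, ...).
    ``burst``: a constant-cycle-length train of ``s1_count`` beats at
    ``s1s1`` (threshold scans re-run it at successively shorter s1s1,
    from ``burst_start`` down by ``burst_step`` to ``burst_min``).
    ``none``: no stimulation.
    """

    kind: str = "burst"
    s1_count: int = 6
    s1s1: float = 300.0
    extra_intervals: tuple = ()
    burst_start: float = 300.0
    burst_step: float = 10.0
    burst_min: float = 80.0
    stim_site: tuple[int, int] = (0, 0)
    stim_amplitude: float = 0.8
    stim_duration: float = 2.0
    stim_radius_px: int = 2
    steady_beats_before_acquisition: int = 30
    start_time: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in ("extrastimulus", "burst", "none"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.s1s1 <= 0:
            raise ValueError("s1s1 must be positive")
        if self.burst_step <= 0:
            raise ValueError("burst_step must be positive")
        if self.steady_beats_before_acquisition < 0:
            raise ValueError("steady_beats_before_acquisition must be >= 0")
        ivals = tuple(float(x) for x in self.extra_intervals)
        if any(x <= 0 for x in ivals):
            raise ValueError("extra intervals must be positive")
        if any(b > a for a, b in zip(ivals, ivals[1:])):
            raise ValueError("extra intervals must be non-increasing")
        self.extra_intervals = ivals

    def stimulus_times(self) -> np.ndarray:
        if self.kind == "none":
            return np.array([])
        times = [self.start_time + i * self.s1s1 for i in range(self.s1_count)]
        if self.kind == "extrastimulus":
            t = times[-1]
            for interval in self.extra_intervals:
                t += interval
                times.append(t)
        return np.asarray(times)


@dataclass
class SimOutput:
    """Simulator result: optical movies, pseudo-ECG, stimulus log, truth.

    ``truth`` holds the noise-free state stacks and everything the
    analysis should recover (per-site activation times and APD80 of the
    clean state variable, the exact calcium decay constant, capture
    flags), so recovery error can be measured exactly.
    """

    vm_movie: OpticalMovie
    cai_movie: OpticalMovie
    pseudo_ecg: np.ndarray
    stimulus_log: list
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# integration engine


class MSEngine:
    """Forward-Euler integrator holding live state; supports checkpointing.

    Used directly for protocols that branch from a common paced state
    (refractory-period scans); :func:`simulate_tissue` is the one-shot
    front end.
    """

    def __init__(self, geometry: TissueGeometry, params: CellModelParams,
                 dt: float | None = None):
        self.geo = geometry
        self.par = params
        dx = geometry.pixel_pitch
        limit = dx * dx / (4.0 * params.diffusion_coeff)
        self.dt = min(dt or 0.1, 0.6 * limit)
        self.exc = geometry.excitable_mask
        h0, w0 = geometry.shape
        self.v = np.zeros((h0, w0))
        self.h = np.ones((h0, w0))
        self.ca = np.zeros((h0, w0))
        self.t = 0.0
        # neighbour-pair weights give internal no-flux walls at the scar
        e = self.exc
        self._w_ns = e[:-1, :] & e[1:, :]
        self._w_ew = e[:, :-1] & e[:, 1:]
        self._dcoef = params.diffusion_coeff / (dx * dx)
        self._ca_gain = params.ca_amplitude_gain / params.tau_ca_eff
        # calcium source is zero exactly at rest (sigmoid re-based at v=0)
        self._ca_src0 = 1.0 / (1.0 + np.exp(0.3 / 0.05))

    def snapshot(self) -> tuple:
        return (self.v.copy(), self.h.copy(), self.ca.copy(), self.t)

    def restore(self, snap: tuple) -> None:
        self.v, self.h, self.ca, self.t = snap[0].copy(), snap[1].copy(), snap[2].copy(), snap[3]

    def _laplacian(self, v: np.ndarray) -> np.ndarray:
        out = np.zeros_like(v)
        dns = (v[1:, :] - v[:-1, :]) * self._w_ns
        out[:-1, :] += dns
        out[1:, :] -= dns
        dew = (v[:, 1:] - v[:, :-1]) * self._w_ew
        out[:, :-1] += dew
        out[:, 1:] -= dew
        return out * self._dcoef

    def step_until(self, t_end: float, stim_current) -> None:
        """Advance to ``t_end``; ``stim_current(t) -> field or None``."""
        par, dt = self.par, self.dt
        n_steps = max(0, int(round((t_end - self.t) / dt)))
        check_every = max(1, int(50.0 / dt))
        for i in range(n_steps):
            v, h, ca = self.v, self.h, self.ca
            dv = h * v * v * (1.0 - v) / par.tau_in - v / par.tau_out + self._laplacian(v)
            stim = stim_current(self.t)
            if stim is not None:
                dv = dv + stim
            above = v >= par.v_gate
            dh = np.where(above, -h / par.tau_close_eff, (1.0 - h) / par.tau_open)
            src = self._ca_gain * np.clip(
                1.0 / (1.0 + np.exp(-(v - 0.3) / 0.05)) - self._ca_src0, 0.0, None)
            dca = src - ca / par.tau_ca_eff
            self.v = np.where(self.exc, v + dt * dv, 0.0)
            self.h = h + dt * dh
            self.ca = np.where(self.exc, ca + dt * dca, 0.0)
            self.t += dt
            if i % check_every == 0 and not np.isfinite(self.v).all():
                raise UnstableIntegrationError(
                    f"non-finite state at t = {self.t:.2f} ms (dt = {dt} ms)"
                )
        if not np.isfinite(self.v).all():
            raise UnstableIntegrationError(f"non-finite state at t = {self.t:.2f} ms")


def _stim_field_builder(geometry: TissueGeometry, stims: list, amplitude: float,
                        duration: float, radius_px: int):
    """Compile (time, site) stimuli into a fast stim_current(t) closure."""
    masks = {}
    h0, w0 = geometry.shape
    rr, cc = np.mgrid[0:h0, 0:w0]
    for _, site in stims:
        site = tuple(site)
        if site not in masks:
            if geometry.scar_mask[site]:
                raise ValueError(f"stimulus site {site} is inside the scar")
            m = ((rr - site[0]) ** 2 + (cc - site[1]) ** 2 <= radius_px**2) & geometry.excitable_mask
            masks[site] = m.astype(float) * amplitude
    stims_sorted = sorted(stims, key=lambda s: s[0])
    times = np.array([s[0] for s in stims_sorted])

    def stim_current(t: float):
        # active stimuli: t in [t_s, t_s + duration)
        i0 = np.searchsorted(times, t - duration, side="right")
        i1 = np.searchsorted(times, t, side="right")
        if i0 == i1:
            return None
        out = None
        for k in range(i0, i1):
            m = masks[tuple(stims_sorted[k][1])]
            out = m if out is None else out + m
        return out

    return stim_current


# ---------------------------------------------------------------------------
# truth extraction helpers (operate on the clean state stacks)


def _upstroke_crossings(trace: np.ndarray, times: np.ndarray, level: float = 0.5,
                        min_sep: float = 40.0) -> np.ndarray:
    """Sub-frame upward level-crossing times of a clean trace."""
    above = trace >= level
    idx = np.flatnonzero(~above[:-1] & above[1:])
    out = []
    for i in idx:
        frac = (level - trace[i]) / (trace[i + 1] - trace[i])
        t = times[i] + frac * (times[i + 1] - times[i])
        if not out or t - out[-1] >= min_sep:
            out.append(t)
    return np.asarray(out)


def _true_apd80(trace: np.ndarray, times: np.ndarray, act_times: np.ndarray) -> np.ndarray:
    """APD at 80% repolarization of the clean v trace for each beat."""
    out = np.full(len(act_times), np.nan)
    for b, t_act in enumerate(act_times):
        i0 = np.searchsorted(times, t_act)
        i1 = np.searchsorted(times, act_times[b + 1]) if b + 1 < len(act_times) else len(times)
        seg = trace[i0:i1]
        if len(seg) < 3:
            continue
        peak = seg.max()
        thr = 0.2 * peak  # baseline is 0 for the clean state variable
        below = np.flatnonzero(seg <= thr)
        below = below[below > np.argmax(seg)]
        if len(below) == 0:
            continue
        j = below[0]
        frac = (seg[j - 1] - thr) / (seg[j - 1] - seg[j])
        t80 = times[i0 + j - 1] + frac * (times[i0 + j] - times[i0 + j - 1])
        out[b] = t80 - t_act
    return out


def _detect_capture(clean_vm: np.ndarray, times: np.ndarray, stim_times: np.ndarray,
                    probe: tuple[int, int], window: float = 150.0) -> list[bool]:
    trace = clean_vm[:, probe[0], probe[1]]
    acts = _upstroke_crossings(trace, times, min_sep=20.0)
    flags = []
    for k, t_s in enumerate(stim_times):
        t_hi = min(t_s + window, stim_times[k + 1] + 5.0 if k + 1 < len(stim_times) else np.inf)
        flags.append(bool(np.any((acts > t_s) & (acts <= t_hi))))
    return flags


def _pick_probe(geometry: TissueGeometry, stim_site: tuple[int, int],
                min_dist_px: float = 8.0) -> tuple[int, int]:
    rr, cc = np.mgrid[0:geometry.height, 0:geometry.width]
    d2 = (rr - stim_site[0]) ** 2 + (cc - stim_site[1]) ** 2
    d2 = np.where(geometry.excitable_mask, d2, -1)
    cand = d2 >= min_dist_px**2
    if not cand.any():
        raise ValueError("no excitable probe site far enough from the stimulus")
    # nearest excitable site beyond the distance: deterministic choice
    flat = np.where(cand, d2, np.inf).argmin()
    return np.unravel_index(flat, d2.shape)


# ---------------------------------------------------------------------------
# public operations


def simulate_tissue(
    geometry: TissueGeometry,
    params: CellModelParams,
    protocol: PacingProtocol,
    noise_snr_db: float = np.inf,
    seed: int = 0,
    frame_interval: float = 2.0,
    record_tail_ms: float = 200.0,
    extra_stimuli: list | None = None,
    electrodes: list | None = None,
    dt: float | None = None,
    keep_truth_stacks: bool = True,
    compute_ecg: bool = True,
) -> SimOutput:
    """Run a paced tissue simulation and emit camera-like recordings.

    Voltage fluorescence is emitted with inverted polarity (the
    voltage-dye convention); scar pixels carry baseline plus noise only.
    Identical seed and inputs give identical output.
    """
    stim_times = protocol.stimulus_times()
    stims = [(float(t), tuple(protocol.stim_site)) for t in stim_times]
    if extra_stimuli:
        stims += [(float(t), tuple(site)) for t, site in extra_stimuli]
    stims.sort(key=lambda s: s[0])
    t_end = (stims[-1][0] if stims else 0.0) + record_tail_ms

    engine = MSEngine(geometry, params, dt=dt)
    if stims:
        stim_fn = _stim_field_builder(geometry, stims, protocol.stim_amplitude,
                                      protocol.stim_duration, protocol.stim_radius_px)
    else:
        stim_fn = lambda t: None

    n_frames = max(2, int(round(t_end / frame_interval)) + 1)
    times = np.arange(n_frames) * frame_interval
    h0, w0 = geometry.shape
    clean_vm = np.zeros((n_frames, h0, w0), dtype=np.float32)
    clean_ca = np.zeros((n_frames, h0, w0), dtype=np.float32)
    for k in range(n_frames):
        engine.step_until(times[k], stim_fn)
        clean_vm[k] = engine.v
        clean_ca[k] = engine.ca

    rng = np.random.default_rng(seed)
    vm_gain, ca_gain, vm_base, ca_base = 0.8, 0.8, 1.0, 0.1
    f_vm = vm_base - vm_gain * clean_vm.astype(np.float64)
    f_ca = ca_base + ca_gain * clean_ca.astype(np.float64)
    # scar emits no signal: reset to baseline before noise
    scar = geometry.scar_mask
    f_vm[:, scar] = vm_base
    f_ca[:, scar] = ca_base
    if np.isfinite(noise_snr_db):
        # SNR (dB) defined on peak-to-peak signal over noise SD
        sigma_vm = vm_gain / 10.0 ** (noise_snr_db / 20.0)
        sigma_ca = ca_gain / 10.0 ** (noise_snr_db / 20.0)
        f_vm += rng.normal(0.0, sigma_vm, f_vm.shape)
        f_ca += rng.normal(0.0, sigma_ca, f_ca.shape)

    meta = {"seed": seed, "noise_snr_db": noise_snr_db, "protocol_kind": protocol.kind,
            "s1s1": protocol.s1s1, "internal_dt_ms": engine.dt}
    vm_movie = OpticalMovie(f_vm, frame_interval, geometry.pixel_pitch, "vm",
                            "inverted", dict(meta))
    cai_movie = OpticalMovie(f_ca, frame_interval, geometry.pixel_pitch, "cai",
                             "upright", dict(meta))

    if compute_ecg:
        if electrodes is None:
            electrodes = default_electrodes(geometry)
        # far field from the clean state variable (electrodes see V, not dye noise)
        state_movie = OpticalMovie(clean_vm.astype(np.float64), frame_interval,
                                   geometry.pixel_pitch, "vm", "upright")
        ecg = compute_pseudo_ecg(state_movie, electrodes)
    else:
        ecg = np.zeros(n_frames)

    # stimulus log with capture flags from the clean state
    stimulus_log = []
    if stims:
        probe = _pick_probe(geometry, protocol.stim_site)
        flags = _detect_capture(clean_vm, times, np.array([s[0] for s in stims]), probe)
        stimulus_log = [(t, site, cap) for (t, site), cap in zip(stims, flags)]

    truth: dict = {
        "tau_ca": params.tau_ca_eff,
        "plane_wave_speed": params.plane_wave_speed(),
        "frame_times": times,
        "stim_times": np.array([s[0] for s in stims]),
    }
    if keep_truth_stacks:
        truth["clean_vm"] = clean_vm
        truth["clean_cai"] = clean_ca
    return SimOutput(vm_movie, cai_movie, ecg, stimulus_log, truth)


def default_electrodes(geometry: TissueGeometry) -> list[tuple[float, float, float]]:
    """Three electrodes around the mapped field, slightly off-plane (mm)."""
    ext_h, ext_w = geometry.physical_extent_mm()
    return [
        (-0.2 * ext_h, 0.5 * ext_w, 5.0),
        (1.2 * ext_h, 0.5 * ext_w, 5.0),
        (0.5 * ext_h, 1.2 * ext_w, 5.0),
    ]


def compute_pseudo_ecg(vm_movie: OpticalMovie, electrodes: list,
                       lead: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Far-field pseudo-ECG from a voltage movie.

    For each electrode the unipolar signal is the volume-conductor sum
    sum_pixels grad(V) . grad(1/r); the returned trace is the difference
    between the ``lead`` electrode pair.  Linear in V.
    """
    if len(electrodes) < 2:
        raise ValueError("need at least two electrodes")
    data = vm_movie.data
    pitch = vm_movie.pixel_pitch
    n_t, h0, w0 = data.shape
    yy, xx = np.mgrid[0:h0, 0:w0]
    py, px = yy * pitch, xx * pitch
    kernels = []
    for (ey, ex, ez) in electrodes:
        dy, dx_, dz = py - ey, px - ex, 0.0 - ez
        r = np.sqrt(dy * dy + dx_ * dx_ + dz * dz)
        if np.any(r < 1e-9):
            raise ValueError("electrode coincides with a pixel center (singular 1/r)")
        r3 = r**3
        kernels.append((-dy / r3, -dx_ / r3))  # grad of 1/r
    gy, gx = np.gradient(data, pitch, axis=(1, 2))
    uni = np.empty((len(electrodes), n_t))
    for i, (ky, kx) in enumerate(kernels):
        uni[i] = np.tensordot(gy, ky, axes=([1, 2], [0, 1])) + \
                 np.tensordot(gx, kx, axes=([1, 2], [0, 1]))
    i, j = lead
    return uni[i] - uni[j]


def measure_true_erp(
    geometry: TissueGeometry,
    params: CellModelParams,
    s1s1: float = 300.0,
    s2_start: float = 200.0,
    s2_step: float = 2.0,
    s2_min: float = 40.0,
    s1_count: int = 6,
    stim_site: tuple[int, int] | None = None,
    stim_amplitude: float = 0.8,
    dt: float | None = None,
    strategy: str = "descend",
) -> float:
    """Effective refractory period by a premature-stimulus scan.

    Runs the S1 drive train once, checkpoints the tissue state at the
    last S1, then replays a single premature S2 per trial.  ERP is the
    longest interval that fails to elicit a propagated response (an
    activation beyond a fixed distance from the stimulus site).
    ``strategy="descend"`` scans from ``s2_start`` down by ``s2_step``
    (the bench protocol); ``"bisect"`` brackets the same boundary in
    O(log) trials, exploiting the monotonicity of capture in the
    coupling interval.  Capture at the smallest scanned interval raises
    ``ERP below scan range``.
    """
    if s2_step <= 0:
        raise ValueError("s2_step must be positive")
    if stim_site is None:
        stim_site = (geometry.height // 2, 2)
    proto = PacingProtocol(kind="burst", s1_count=s1_count, s1s1=s1s1,
                           stim_site=stim_site, stim_amplitude=stim_amplitude)
    stims = [(float(t), tuple(stim_site)) for t in proto.stimulus_times()]
    engine = MSEngine(geometry, params, dt=dt)
    stim_fn = _stim_field_builder(geometry, stims, proto.stim_amplitude,
                                  proto.stim_duration, proto.stim_radius_px)
    t_last_s1 = stims[-1][0]
    engine.step_until(t_last_s1, stim_fn)
    base_snap = engine.snapshot()
    # capture = a propagated response: most of the tissue re-activates.
    # (A single distal probe can be fooled by local re-excitation blips
    # near the refractory boundary.)
    rr, cc = np.mgrid[0:geometry.height, 0:geometry.width]
    far = ((rr - stim_site[0]) ** 2 + (cc - stim_site[1]) ** 2 > 4.0**2) \
        & geometry.excitable_mask

    def s2_captures(interval: float, window: float = 150.0,
                    capture_fraction: float = 0.5) -> bool:
        engine.restore(base_snap)
        t_s2 = t_last_s1 + interval
        trial = stims + [(t_s2, tuple(stim_site))]
        fn = _stim_field_builder(geometry, trial, proto.stim_amplitude,
                                 proto.stim_duration, proto.stim_radius_px)
        engine.step_until(t_s2, fn)
        # count only NEW activations: a cell must first be repolarized
        # (below 0.45, with hysteresis) and then rise above 0.5 —
        # lingering S1 plateaus are not S2 captures
        activated = np.zeros_like(far)
        was_below = engine.v < 0.45
        n_chunks = int(round(window / 2.0))
        for _ in range(n_chunks):
            engine.step_until(engine.t + 2.0, fn)
            activated |= was_below & (engine.v >= 0.5)
            was_below |= engine.v < 0.45
        frac = activated[far].mean()
        return bool(frac >= capture_fraction)

    if strategy == "descend":
        interval = float(s2_start)
        first = True
        while interval >= s2_min - 1e-9:
            captured = s2_captures(interval)
            if first and not captured:
                raise SimulationError(
                    f"S2 at the scan start ({s2_start} ms) did not capture; start the scan longer"
                )
            first = False
            if not captured:
                return interval
            interval -= s2_step
        raise SimulationError("ERP below scan range: capture at the smallest scanned interval")
    if strategy != "bisect":
        raise ValueError(f"unknown scan strategy {strategy!r}")
    # bisect on the scan grid: lo always fails (ERP candidate), hi captures
    if not s2_captures(s2_start):
        raise SimulationError(
            f"S2 at the scan start ({s2_start} ms) did not capture; start the scan longer"
        )
    n_steps = int((s2_start - s2_min) // s2_step)
    lo_k, hi_k = n_steps, 0  # interval(k) = s2_start - k*s2_step
    if s2_captures(s2_start - lo_k * s2_step):
        raise SimulationError("ERP below scan range: capture at the smallest scanned interval")
    while lo_k - hi_k > 1:
        mid = (lo_k + hi_k) // 2
        if s2_captures(s2_start - mid * s2_step):
            hi_k = mid
        else:
            lo_k = mid
    return float(s2_start - lo_k * s2_step)


@dataclass
class EctopyEvents:
    """Delivered and suppressed spontaneous focal beats."""

    delivered: np.ndarray
    suppressed: np.ndarray
    origin: tuple[int, int]
    rate_per_min: float


def inject_ectopy(
    geometry: TissueGeometry,
    params: CellModelParams,
    rate_per_min: float,
    origin: tuple[int, int],
    duration_ms: float,
    seed: int = 0,
    paced_times: np.ndarray | None = None,
    refractory_ms: float | None = None,
) -> EctopyEvents:
    """Draw spontaneous ectopic beat times from a Poisson process.

    Candidate times falling within the refractory period of any earlier
    delivered beat (paced or ectopic) are suppressed.  The origin must
    lie in the peri-infarct border zone, never in the scar.
    """
    if rate_per_min < 0:
        raise ValueError("rate must be non-negative")
    origin = tuple(origin)
    if geometry.scar_mask[origin]:
        raise ValueError(f"ectopic origin {origin} is inside the scar")
    if geometry.border_zone_mask.any() and not geometry.border_zone_mask[origin]:
        raise ValueError(f"ectopic origin {origin} is outside the border zone")
    if refractory_ms is None:
        refractory_ms = params.apd_restitution(300.0) + 40.0
    rng = np.random.default_rng(seed)
    rate_per_ms = rate_per_min / 60000.0
    candidates = []
    if rate_per_ms > 0:
        t = 0.0
        while True:
            t += rng.exponential(1.0 / rate_per_ms)
            if t >= duration_ms:
                break
            candidates.append(t)
    paced = np.sort(np.asarray(paced_times, dtype=float)) if paced_times is not None else np.array([])
    delivered, suppressed = [], []
    all_beats = list(paced)
    for t in candidates:
        prior = [b for b in all_beats if b <= t]
        if prior and t - max(prior) < refractory_ms:
            suppressed.append(t)
        else:
            delivered.append(t)
            all_beats.append(t)
            all_beats.sort()
    return EctopyEvents(np.asarray(delivered), np.asarray(suppressed),
                        origin, rate_per_min)
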