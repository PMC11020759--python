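"""Per-site, per-beat electrophysiological features.

From a normalized, depolarization-positive trace this module extracts
activation times (maximal upstroke velocity, refined to sub-frame
precision), action-potential / calcium-transient durations at a
fractional repolarization level (APD80/CaTD80 by default), beat
amplitudes and diastolic intervals, the monoexponential calcium decay
constant tau, and the effective refractory period from a premature
stimulus scan.  Site aggregation enforces the study's minimum of 25
analyzable (non-infarcted) sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .movie import InsufficientSitesError, OpticalMovie, QualityMask

#: minimum dynamic range below which a trace is considered flat
_FLAT_EPS = 1e-9


# ---------------------------------------------------------------------------
# activation detection


def detect_activations(
    trace: np.ndarray,
    frame_interval: float = 2.0,
    min_interval: float = 80.0,
    slope_fraction: float = 0.35,
    amplitude_fraction: float = 0.3,
    stim_times: np.ndarray | None = None,
    paced_latency: float = 40.0,
):
    """Activation times of a normalized depolarization-positive trace.

    Activation is the time of maximal first derivative within each beat,
    refined by parabolic interpolation of the derivative peak; beats are
    separated by a ``min_interval`` refractory guard, and a candidate
    must be followed by a rise of at least ``amplitude_fraction`` of the
    trace's robust range (this rejects noise spikes on slow-upstroke
    channels such as calcium).  A flat trace yields an empty list.
    When ``stim_times`` is given, also returns a boolean ``paced`` array
    marking activations that follow a stimulus within ``paced_latency``
    ms.
    """
    trace = np.asarray(trace, dtype=float)
    if np.ptp(trace) < _FLAT_EPS:
        times = np.array([])
        return (times, np.array([], dtype=bool)) if stim_times is not None else times
    d = np.diff(trace)
    height = slope_fraction * d.max()
    if height <= 0:
        times = np.array([])
        return (times, np.array([], dtype=bool)) if stim_times is not None else times
    distance = max(1, int(round(min_interval / frame_interval)))
    peaks, _ = find_peaks(d, height=height, distance=distance)
    # amplitude gate: a real beat rises well above its local baseline
    robust_range = np.percentile(trace, 98) - np.percentile(trace, 2)
    win = max(2, int(round(min_interval / frame_interval)))
    kept = []
    for i in peaks:
        base = np.median(trace[max(0, i - 10):i + 1])
        peak_val = trace[i:min(len(trace), i + win)].max()
        if peak_val - base >= amplitude_fraction * robust_range:
            kept.append(i)
    peaks = kept
    times = []
    for i in peaks:
        # derivative sample i sits between frames i and i+1
        t = (i + 0.5) * frame_interval
        if 0 < i < len(d) - 1:
            denom = d[i - 1] - 2.0 * d[i] + d[i + 1]
            if abs(denom) > 1e-12:
                delta = 0.5 * (d[i - 1] - d[i + 1]) / denom
                t += np.clip(delta, -1.0, 1.0) * frame_interval
        times.append(t)
    times = np.asarray(times)
    if stim_times is None:
        return times
    stim_times = np.asarray(stim_times, dtype=float)
    paced = np.zeros(len(times), dtype=bool)
    for k, t in enumerate(times):
        prior = stim_times[stim_times <= t]
        paced[k] = len(prior) > 0 and (t - prior[-1]) <= paced_latency
    return times, paced


# ---------------------------------------------------------------------------
# duration at a repolarization level


def compute_duration(
    trace: np.ndarray,
    activation_time: float,
    level: float = 0.8,
    frame_interval: float = 2.0,
    next_activation: float | None = None,
    baseline_window: float = 20.0,
) -> tuple[float, bool]:
    """Duration from activation to ``level`` (default 80%) repolarization.

    The beat's baseline is the median of the ``baseline_window`` ms
    preceding the upstroke; the repolarization threshold is
    ``peak - level * (peak - baseline)``, crossed downward, with linear
    interpolation between frames.  Returns ``(duration_ms, valid)``;
    a beat that never repolarizes before the next activation is flagged
    invalid rather than raising.
    """
    if not (0.0 < level <= 1.0):
        raise ValueError("level must be in (0, 1]")
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    times = np.arange(n) * frame_interval
    i_act = int(np.searchsorted(times, activation_time))
    if i_act < 1 or i_act >= n - 1:
        return np.nan, False
    i_base0 = max(0, i_act - int(round(baseline_window / frame_interval)))
    baseline = float(np.median(trace[i_base0:i_act])) if i_act > i_base0 else trace[i_act - 1]
    i_end = n if next_activation is None else int(np.searchsorted(times, next_activation))
    seg = trace[i_act:i_end]
    if len(seg) < 3:
        return np.nan, False
    i_peak = int(np.argmax(seg))
    peak = float(seg[i_peak])
    if peak - baseline < _FLAT_EPS:
        return np.nan, False
    thr = peak - level * (peak - baseline)
    below = np.flatnonzero(seg[i_peak:] <= thr)
    if len(below) == 0:
        return np.nan, False
    j = i_peak + below[0]
    if j == 0:
        return np.nan, False
    frac = (seg[j - 1] - thr) / (seg[j - 1] - seg[j])
    t_cross = times[i_act + j - 1] + frac * frame_interval
    return float(t_cross - activation_time), True


# ---------------------------------------------------------------------------
# per-movie beat feature table


def beat_feature_table(
    movie: OpticalMovie,
    mask: QualityMask | None = None,
    stim_times: np.ndarray | None = None,
    level: float = 0.8,
    min_interval: float = 80.0,
    site_stride: int = 1,
) -> pd.DataFrame:
    """Extract activation/duration/amplitude/DI for every valid site.

    Returns a tidy frame with columns ``row, col, beat, activation_time,
    duration, amplitude, di, paced, valid``.  ``site_stride`` subsamples
    the grid for speed on large movies.
    """
    data = movie.data
    n_t, h0, w0 = data.shape
    valid = np.ones((h0, w0), dtype=bool) if mask is None else mask.valid
    rows = []
    for r in range(0, h0, site_stride):
        for c in range(0, w0, site_stride):
            if not valid[r, c]:
                continue
            trace = data[:, r, c]
            res = detect_activations(trace, movie.frame_interval, min_interval,
                                     stim_times=stim_times)
            acts, paced = res if stim_times is not None else (res, None)
            prev_end = None
            for b, t_act in enumerate(acts):
                nxt = acts[b + 1] if b + 1 < len(acts) else None
                dur, ok = compute_duration(trace, t_act, level,
                                           movie.frame_interval, nxt)
                i_act = int(t_act / movie.frame_interval)
                i_end = int(nxt / movie.frame_interval) if nxt else n_t
                seg = trace[i_act:i_end]
                amp = float(seg.max() - np.median(trace[max(0, i_act - 10):i_act])) if len(seg) else np.nan
                di = (t_act - prev_end) if (prev_end is not None) else np.nan
                rows.append((r, c, b, t_act, dur if ok else np.nan, amp, di,
                             bool(paced[b]) if paced is not None else True, ok))
                prev_end = t_act + dur if ok else None
    return pd.DataFrame(rows, columns=["row", "col", "beat", "activation_time",
                                       "duration", "amplitude", "di", "paced", "valid"])


# ---------------------------------------------------------------------------
# calcium decay tau


@dataclass
class TauFit:
    """Monoexponential decay fit A exp(-(t - t0)/tau) + C."""

    tau: float
    amplitude: float
    offset: float
    fit_window: tuple[float, float]
    rss: float
    valid: bool
    message: str = ""


def fit_ca_decay(
    trace: np.ndarray,
    activation_time: float,
    frame_interval: float = 2.0,
    start_level: float = 0.2,
    recovery_level: float = 0.95,
    tau_bounds: tuple[float, float] = (1.0, 1000.0),
) -> TauFit:
    """Fit the diastolic calcium decay of one (final) beat.

    The fit starts at the ``start_level`` repolarization crossing (20%
    down from the peak by default) and ends at ``recovery_level``
    recovery toward baseline, or at the end of the trace.  The estimate
    is invariant under affine rescaling of the trace.
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    times = np.arange(n) * frame_interval
    i_act = int(np.searchsorted(times, activation_time))
    if i_act < 1 or i_act >= n - 2:
        return TauFit(np.nan, np.nan, np.nan, (np.nan, np.nan), np.nan, False,
                      "activation outside trace")
    from scipy.ndimage import uniform_filter1d

    # the fit window is chosen on a lightly smoothed copy so noisy
    # threshold crossings do not truncate it; the fit itself uses raw data
    smooth = uniform_filter1d(trace, size=5)
    # The baseline anchors the fit's offset, so it needs many samples
    # and no contamination from the previous transient's tail.  Since
    # the fitted beat is the final one of its train, the most recovered
    # stretch is the END of the trace: use its last samples, as far past
    # the peak as the recording allows; a pre-upstroke window is the
    # fallback for recordings truncated right after the transient.
    i_peak_rough = i_act + int(np.argmax(smooth[i_act:]))
    i_tail = max(i_peak_rough + int(round(150.0 / frame_interval)), n - 60)
    if n - i_tail >= 12:
        baseline = float(np.median(trace[i_tail:]))
    else:
        baseline = float(np.median(trace[max(0, i_act - 50):i_act]))
    seg = smooth[i_act:]
    i_peak = int(np.argmax(seg)) + i_act
    peak = float(smooth[i_peak])
    if peak - baseline < _FLAT_EPS:
        return TauFit(np.nan, np.nan, np.nan, (np.nan, np.nan), np.nan, False, "flat beat")
    thr_start = peak - start_level * (peak - baseline)
    after_peak = smooth[i_peak:]
    below = np.flatnonzero(after_peak <= thr_start)
    if len(below) == 0:
        return TauFit(np.nan, np.nan, np.nan, (np.nan, np.nan), np.nan, False,
                      "never reaches the start level")
    i0 = i_peak + below[0]
    thr_end = baseline + (1.0 - recovery_level) * (peak - baseline)
    below_end = np.flatnonzero(smooth[i0:] <= thr_end)
    # small margin past the crossing: ending exactly where a (possibly
    # noise-driven) downward excursion is detected would correlate the
    # window choice with the noise and bias tau upward
    i1 = (i0 + below_end[0] + 11) if len(below_end) else n
    if i1 - i0 < 4:
        i1 = min(n, i0 + 4)
    if i1 - i0 < 4:
        return TauFit(np.nan, np.nan, np.nan, (np.nan, np.nan), np.nan, False,
                      "too few samples in fit window")
    t_fit = times[i0:i1] - times[i0]
    y_fit = trace[i0:i1]

    # the offset is anchored to the measured diastolic baseline: letting
    # it float trades off against tau on windows that stop at 95%
    # recovery and biases the estimate upward
    def model(t, a, tau):
        return a * np.exp(-t / tau) + baseline

    a0 = max(y_fit[0] - baseline, _FLAT_EPS)
    tau0 = max(t_fit[-1] / 3.0, 2.0)
    try:
        popt, _ = curve_fit(model, t_fit, y_fit, p0=(a0, tau0),
                            bounds=([0.0, 0.5], [np.inf, 2000.0]), maxfev=5000)
    except RuntimeError as exc:
        return TauFit(np.nan, np.nan, np.nan, (times[i0], times[i1 - 1]), np.nan,
                      False, f"fit did not converge: {exc}")
    a, tau = popt
    c = baseline
    rss = float(np.sum((model(t_fit, *popt) - y_fit) ** 2))
    ok = bool(tau_bounds[0] < tau < tau_bounds[1] and a > 0)
    return TauFit(float(tau), float(a), float(c), (float(times[i0]), float(times[i1 - 1])),
                  rss, ok, "" if ok else f"tau {tau:.1f} ms outside {tau_bounds}")


# ---------------------------------------------------------------------------
# aggregation and ERP


def aggregate_sites(
    features: pd.DataFrame,
    value: str = "duration",
    min_sites: int = 25,
    steady_from_beat: int = 0,
) -> dict:
    """Per-heart mean/SD of a feature over valid sites.

    Each site contributes its mean over steady-state beats (index >=
    ``steady_from_beat``); fewer than ``min_sites`` analyzable sites is
    an explicit failure, mirroring the >= 25 non-infarcted-site rule.
    """
    good = features[(features["valid"]) & (features["beat"] >= steady_from_beat)]
    good = good.dropna(subset=[value])
    site_means = good.groupby(["row", "col"])[value].mean()
    if len(site_means) < min_sites:
        raise InsufficientSitesError(
            f"insufficient analyzable sites: {len(site_means)} < {min_sites}"
        )
    return {
        "mean": float(site_means.mean()),
        "sd": float(site_means.std(ddof=1)),
        "n_sites": int(len(site_means)),
    }


def measure_erp_from_protocol(
    intervals: np.ndarray,
    captured: np.ndarray,
) -> float:
    """ERP from a premature-stimulus scan: the longest non-captured interval.

    ``intervals`` and ``captured`` come from per-trial capture detection
    (see :func:`capture_in_movie`).  All-captured scans raise: the ERP
    lies below the scanned range.
    """
    intervals = np.asarray(intervals, dtype=float)
    captured = np.asarray(captured, dtype=bool)
    if len(intervals) != len(captured) or len(intervals) == 0:
        raise ValueError("intervals and captured must be equal-length, non-empty")
    failed = intervals[~captured]
    if len(failed) == 0:
        raise RuntimeError("ERP below scan range: every scanned interval captured")
    return float(failed.max())


def capture_in_movie(
    movie: OpticalMovie,
    stim_site: tuple[int, int],
    stim_time: float,
    min_distance_px: float = 8.0,
    window_ms: float = 160.0,
) -> bool:
    """Did a stimulus at ``stim_time`` propagate beyond ``min_distance_px``?

    Activation only near the stimulus electrode counts as non-capture
    (local-response ambiguity is resolved conservatively).
    """
    data = movie.data
    h0, w0 = data.shape[1:]
    rr, cc = np.mgrid[0:h0, 0:w0]
    far = (rr - stim_site[0]) ** 2 + (cc - stim_site[1]) ** 2 >= min_distance_px**2
    if not far.any():
        raise ValueError("movie too small for the capture probe distance")
    # probe: the far pixel with the largest dynamic range (robust to scar)
    ranges = np.where(far, data.max(axis=0) - data.min(axis=0), -1.0)
    probe = np.unravel_index(int(ranges.argmax()), ranges.shape)
    acts = detect_activations(data[:, probe[0], probe[1]], movie.frame_interval,
                              min_interval=40.0)
    acts = np.asarray(acts)
    return bool(np.any((acts > stim_time) & (acts <= stim_time + window_ms)))
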