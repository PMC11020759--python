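"""Conditioning of raw fluorescence into analyzable normalized traces.

Raw optical-mapping signals carry pixel-to-pixel gain differences,
inverted polarity on the voltage channel (voltage dyes dim on
depolarization), slow photobleaching drift, and shot noise.  This
module flips polarity so depolarization is positive, removes drift,
smooths spatially and temporally with strictly zero-phase filters (so
activation times are never biased), and normalizes each pixel to [0, 1]
with robust percentiles.  The per-pixel SNR map then defines the
valid-pixel mask; the infarct zone's obscure signals fall below
threshold, which is how the scar is excluded from every downstream
analysis.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter, uniform_filter1d
from scipy.optimize import curve_fit

from .movie import InsufficientSitesError, OpticalMovie, QualityMask

#: robust normalization percentiles (low, high)
NORM_PERCENTILES = (2.0, 98.0)


def preprocess(
    movie: OpticalMovie,
    spatial_kernel_px: int = 1,
    temporal_window_frames: int = 1,
    detrend: str = "none",
) -> OpticalMovie:
    """Normalize a movie to [0, 1] per pixel, depolarization-positive.

    ``spatial_kernel_px`` and ``temporal_window_frames`` must be odd;
    both filters are symmetric moving averages (zero phase: no frame
    shifts).  ``detrend`` removes per-pixel slow drift before
    normalization: ``linear`` subtracts a least-squares line,
    ``exponential`` divides out a fitted monoexponential bleach curve.
    Identity settings (kernel 1, window 1, no detrend) leave an already
    normalized upright movie unchanged.

    Pixels with no dynamic range are left at 0 and recorded in
    ``metadata["degenerate_mask"]`` rather than divided by zero.
    """
    if spatial_kernel_px < 1 or spatial_kernel_px % 2 == 0:
        raise ValueError("spatial_kernel_px must be odd and >= 1")
    if temporal_window_frames < 1 or temporal_window_frames % 2 == 0:
        raise ValueError("temporal_window_frames must be odd and >= 1")
    if detrend not in ("none", "linear", "exponential"):
        raise ValueError(f"unknown detrend mode {detrend!r}")

    data = movie.data.astype(np.float64, copy=True)
    if movie.polarity == "inverted":
        data = -data  # depolarization becomes positive
    if detrend != "none":
        data = _detrend(data, detrend)
    if spatial_kernel_px > 1:
        data = uniform_filter(data, size=(1, spatial_kernel_px, spatial_kernel_px),
                              mode="nearest")
    if temporal_window_frames > 1:
        data = uniform_filter1d(data, size=temporal_window_frames, axis=0,
                                mode="nearest")

    lo = np.percentile(data, NORM_PERCENTILES[0], axis=0)
    hi = np.percentile(data, NORM_PERCENTILES[1], axis=0)
    span = hi - lo
    degenerate = span < 1e-12
    span_safe = np.where(degenerate, 1.0, span)
    out = np.clip((data - lo) / span_safe, 0.0, 1.0)
    out[:, degenerate] = 0.0

    meta = dict(movie.metadata)
    meta["normalized"] = True
    meta["degenerate_mask"] = degenerate
    return OpticalMovie(out, movie.frame_interval, movie.pixel_pitch,
                        movie.channel, "upright", meta)


def _detrend(data: np.ndarray, mode: str) -> np.ndarray:
    n_t = data.shape[0]
    t = np.arange(n_t, dtype=float)
    flat = data.reshape(n_t, -1)
    if mode == "linear":
        # fit the line to the lower envelope (diastolic baseline) so the
        # beat shape cannot leak into the estimated slope
        from scipy.ndimage import minimum_filter1d

        w = max(5, n_t // 10)
        envelope = minimum_filter1d(flat, size=w, axis=0, mode="nearest")
        design = np.vstack([t, np.ones(n_t)]).T
        coef, *_ = np.linalg.lstsq(design, envelope, rcond=None)
        trend = t[:, None] * coef[0][None, :]  # remove slope, keep offset
        return (flat - trend).reshape(data.shape)
    # exponential: one global bleach curve fitted to the spatial-mean
    # lower envelope (photobleaching is multiplicative and slow)
    mean_tr = flat.mean(axis=1)
    env = uniform_filter1d(mean_tr, size=max(3, n_t // 8), mode="nearest")

    def bleach(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    try:
        popt, _ = curve_fit(bleach, t, env, p0=(env[0] - env[-1], n_t / 2.0, env[-1]),
                            maxfev=5000)
        curve = bleach(t, *popt)
    except RuntimeError:
        curve = env
    scale = curve / max(curve[0], 1e-12)
    scale = np.clip(scale, 1e-3, None)
    return (flat / scale[:, None]).reshape(data.shape)


def build_quality_mask(
    movie: OpticalMovie,
    snr_threshold_db: float = 10.0,
    min_valid_sites: int = 25,
    manual_include: np.ndarray | None = None,
) -> QualityMask:
    """Per-pixel SNR mask; fails loudly if fewer than 25 sites survive.

    The SNR estimator is the ratio of beat-band variance (5-frame
    smoothed trace) to the high-frequency residual variance
    (first-difference noise estimate), in dB.  It assumes the movie has
    NOT been temporally filtered: smoothing correlates the noise and
    inflates the estimate, so build the mask from the normalized,
    unfiltered movie (``preprocess(movie, 1, 1)``) and apply it to the
    filtered one.  Raising the threshold never adds valid pixels.  The
    default threshold is set so that a simulated infarct at 20 dB
    recording SNR is fully excluded.
    """
    data = movie.data
    smooth = uniform_filter1d(data, size=5, axis=0, mode="nearest")
    signal_power = smooth.var(axis=0)
    resid = np.diff(data - smooth, axis=0)
    noise_power = resid.var(axis=0) / 2.0 + 1e-30
    with np.errstate(divide="ignore"):
        snr_db = 10.0 * np.log10(signal_power / noise_power + 1e-30)
    valid = snr_db >= snr_threshold_db
    degenerate = movie.metadata.get("degenerate_mask")
    if degenerate is not None:
        valid &= ~np.asarray(degenerate, dtype=bool)
    if manual_include is not None:
        valid &= np.asarray(manual_include, dtype=bool)
    mask = QualityMask(valid=valid, snr_map=snr_db, snr_threshold=snr_threshold_db)
    if mask.n_valid < min_valid_sites:
        raise InsufficientSitesError(
            f"insufficient analyzable sites: {mask.n_valid} < {min_valid_sites}"
        )
    return mask
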