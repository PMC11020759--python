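"""Alternans detection, spatial classification, and threshold scans.

Cardiac alternans is a beat-to-beat long-short alternation of action
potential duration or calcium transient amplitude.  Following the
study conventions this package adopts, APD alternans is significant
when consecutive beats differ by more than 10 ms, and calcium
alternans when consecutive-beat amplitudes differ by more than 5%
(percentage relative to the pair mean).  The signed per-site
alternation magnitude (even-beat minus odd-beat) defines a spatial
map: all-one-sign maps are concordant, maps with substantial regions
of both signs are spatially discordant, and the zero-level contour
between opposite-sign regions is the nodal line — the substrate for
functional conduction block.

The alternans *threshold* is the longest pacing cycle length at which
significant alternans appears while decrementing a burst-pacing scan,
evaluated at the site of maximum alternans; scanning stops on loss of
1:1 capture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from skimage import measure

#: significance thresholds: >10 ms for APD, >5% for Ca amplitude
APD_ALTERNANS_THRESHOLD_MS = 10.0
CA_ALTERNANS_THRESHOLD_PCT = 5.0


@dataclass
class AlternansMap:
    """Per-site signed alternation with significance flags.

    ``delta`` is the mean over consecutive beat pairs of (even - odd)
    beat values: ms for APD, % of pair-mean amplitude for calcium.
    ``parity_sign`` is +/-1 where significant, 0 elsewhere.
    """

    delta: np.ndarray
    significant: np.ndarray
    parity_sign: np.ndarray
    channel: str
    threshold: float
    n_pairs: np.ndarray
    nodal_lines: list = field(default_factory=list)

    @property
    def any_significant(self) -> bool:
        return bool(self.significant.any())

    def max_abs_delta(self) -> float:
        if np.all(np.isnan(self.delta)):
            return np.nan
        return float(np.nanmax(np.abs(self.delta)))


def compute_alternans_map(
    features: pd.DataFrame,
    channel: str = "apd",
    grid_shape: tuple[int, int] | None = None,
    min_beats: int = 4,
) -> AlternansMap:
    """Signed beat-to-beat alternation per site from a beat-feature table.

    ``channel="apd"`` uses the ``duration`` column (ms difference);
    ``channel="ca_amplitude"`` uses ``amplitude`` and expresses the
    difference as a percentage of the pair mean.  Sites with fewer than
    ``min_beats`` valid beats are invalid (NaN); an odd trailing beat is
    ignored.
    """
    if channel == "apd":
        col, threshold = "duration", APD_ALTERNANS_THRESHOLD_MS
    elif channel == "ca_amplitude":
        col, threshold = "amplitude", CA_ALTERNANS_THRESHOLD_PCT
    else:
        raise ValueError(f"unknown alternans channel {channel!r}")

    if grid_shape is None:
        grid_shape = (int(features["row"].max()) + 1, int(features["col"].max()) + 1)
    delta = np.full(grid_shape, np.nan)
    n_pairs = np.zeros(grid_shape, dtype=int)

    for (r, c), site in features[features["valid"]].groupby(["row", "col"]):
        vals = site.sort_values("beat")[col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < min_beats:
            continue
        if len(vals) % 2 == 1:
            vals = vals[:-1]
        even, odd = vals[0::2], vals[1::2]
        diffs = even - odd
        if channel == "ca_amplitude":
            pair_means = (even + odd) / 2.0
            pair_means[pair_means == 0] = np.nan
            diffs = 100.0 * diffs / pair_means
        delta[r, c] = float(np.nanmean(diffs))
        n_pairs[r, c] = len(diffs)

    significant = np.abs(delta) > threshold
    significant &= np.isfinite(delta)
    parity = np.where(significant, np.sign(delta), 0.0).astype(int)
    amap = AlternansMap(delta, significant, parity, channel, threshold, n_pairs)
    amap.nodal_lines = _nodal_lines(amap)
    return amap


def _nodal_lines(amap: AlternansMap, smooth_px: int = 3) -> list:
    """Zero-level contours of the smoothed signed map between regions of
    opposite significant sign.  Empty unless both signs occur."""
    if not ((amap.parity_sign > 0).any() and (amap.parity_sign < 0).any()):
        return []
    if min(amap.delta.shape) < 2:
        return []  # contouring needs a 2-D field; a single row has no line
    filled = np.nan_to_num(amap.delta, nan=0.0)
    smoothed = uniform_filter(filled, size=smooth_px, mode="nearest")
    return [c for c in measure.find_contours(smoothed, 0.0) if len(c) >= 2]


def classify_spatial_pattern(
    amap: AlternansMap,
    min_region_px: int = 10,
    min_sites: int = 25,
) -> tuple[str, list]:
    """``none`` / ``concordant`` / ``discordant`` with nodal lines.

    Discordance requires significant sites of both parity signs, each
    sign covering at least ``min_region_px`` pixels (suppresses
    speckle).  Requires at least ``min_sites`` analyzable sites.
    """
    n_valid = int(np.isfinite(amap.delta).sum())
    if n_valid < min_sites:
        raise ValueError(f"alternans map has {n_valid} valid sites < {min_sites}")
    n_pos = int((amap.parity_sign > 0).sum())
    n_neg = int((amap.parity_sign < 0).sum())
    if n_pos + n_neg == 0:
        return "none", []
    if n_pos >= min_region_px and n_neg >= min_region_px:
        return "discordant", amap.nodal_lines
    return "concordant", []


@dataclass
class AlternansThresholdResult:
    """Outcome of a decremental burst-pacing threshold scan."""

    threshold_pcl: float  # NaN when no alternans appeared in range
    scanned_pcls: list
    max_abs_delta: list
    capture_lost_at: float | None = None

    @property
    def found(self) -> bool:
        return np.isfinite(self.threshold_pcl)


def find_alternans_threshold(
    movie_provider,
    pcl_start: float = 300.0,
    pcl_step: float = 10.0,
    pcl_min: float = 80.0,
    channel: str = "apd",
) -> AlternansThresholdResult:
    """Longest PCL at which significant alternans first appears.

    ``movie_provider(pcl)`` must return a steady-state beat-feature
    table for that cycle length, or ``None`` on loss of 1:1 capture
    (which stops the scan).  Significance is judged at the site of
    maximum alternans magnitude.
    """
    if pcl_step <= 0:
        raise ValueError("pcl_step must be positive")
    scanned, maxima = [], []
    capture_lost_at = None
    threshold = np.nan
    pcl = float(pcl_start)
    while pcl >= pcl_min - 1e-9:
        feats = movie_provider(pcl)
        if feats is None:
            capture_lost_at = pcl
            break
        amap = compute_alternans_map(feats, channel=channel)
        scanned.append(pcl)
        maxima.append(amap.max_abs_delta())
        if amap.any_significant:
            threshold = pcl
            break
        pcl -= pcl_step
    return AlternansThresholdResult(threshold, scanned, maxima, capture_lost_at)


def cable_movie_provider(rmap, n_beats: int = 60, n_sites: int = 40,
                         discard: int = 40, min_capture_fraction: float = 0.95,
                         site_apd_shift=None):
    """Adapter: restitution-map runs as a threshold-scan provider.

    Returns a callable usable with :func:`find_alternans_threshold`;
    the APD series is reshaped into the beat-feature layout (sites on
    one row).  With ``site_apd_shift`` given, sites iterate the map
    independently with heterogeneous apd_max (the mapped-field spread
    that max-alternans-site selection presumes); otherwise a coupled
    conducting cable is run.  Loss of 1:1 capture maps to ``None``.
    """
    from .restitution import run_independent_sites, run_restitution_cable

    def provider(pcl: float):
        if site_apd_shift is not None:
            res = run_independent_sites(rmap, pcl, n_beats, site_apd_shift)
        else:
            res = run_restitution_cable(rmap, pcl, n_beats, n_sites=n_sites)
        steady = res[res["beat"] >= discard]
        frac_captured = steady["captured"].mean()
        if frac_captured < min_capture_fraction:
            return None
        feats = pd.DataFrame({
            "row": 0,
            "col": steady["site"].astype(int),
            "beat": steady["beat"].astype(int),
            "activation_time": steady["activation_time"],
            "duration": steady["apd"],
            "amplitude": steady["apd"],
            "di": steady["di"],
            "paced": True,
            "valid": steady["captured"].astype(bool),
        })
        return feats

    return provider
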