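"""Isochrone maps, conduction velocity, block lines, phase maps, and
phase-singularity (reentry pivot) tracking.

An isochrone map assigns each site the activation time of one beat
relative to the beat's earliest activation; its local gradient gives
the conduction velocity field (v = grad T / |grad T|^2, the slowness
inversion).  Steep activation-time jumps between neighbouring sites
mark conduction block — fixed when scar-adjacent, functional when it
co-localizes with an alternans nodal line.  For reentrant rhythms the
instantaneous phase of each pixel (Hilbert analytic signal) defines a
phase field whose topological defects — points where the closed-loop
phase winding is +/-2 pi — are the pivots of spiral-wave reentry;
these are detected per frame and linked into tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .movie import OpticalMovie


# ---------------------------------------------------------------------------
# isochrones


@dataclass
class IsochroneMap:
    """Activation-time map of one beat (ms, relative to earliest site)."""

    activation_time: np.ndarray
    reference_time: float
    unactivated: np.ndarray
    pixel_pitch: float = 0.25

    @property
    def shape(self) -> tuple[int, int]:
        return self.activation_time.shape


def build_isochrone(
    features: pd.DataFrame,
    beat_index: int,
    grid_shape: tuple[int, int],
    pixel_pitch: float = 0.25,
    valid_mask: np.ndarray | None = None,
) -> IsochroneMap:
    """Isochrone map for one beat from a beat-feature table.

    Sites without a detected activation for that beat (scar, invalid,
    or genuinely blocked) are flagged ``unactivated``; with a supplied
    ``valid_mask`` those blocked-but-valid sites can later be told
    apart from invalid ones.
    """
    act = np.full(grid_shape, np.nan)
    sub = features[features["beat"] == beat_index]
    for _, rowdat in sub.iterrows():
        act[int(rowdat["row"]), int(rowdat["col"])] = rowdat["activation_time"]
    finite = np.isfinite(act)
    if not finite.any():
        return IsochroneMap(act, np.nan, ~finite, pixel_pitch)
    ref = float(np.nanmin(act))
    rel = act - ref
    if valid_mask is not None:
        rel[~valid_mask] = np.nan
    return IsochroneMap(rel, ref, ~np.isfinite(rel), pixel_pitch)


def isochrone_in_window(
    features: pd.DataFrame,
    t_start: float,
    t_end: float,
    grid_shape: tuple[int, int],
    pixel_pitch: float = 0.25,
) -> IsochroneMap:
    """Isochrone of the beat whose activations fall in a time window.

    Useful when sites do not share beat indices (e.g. a premature beat
    that conducts only part-way before blocking): each site contributes
    its first activation inside ``[t_start, t_end)``.
    """
    act = np.full(grid_shape, np.nan)
    sub = features[(features["activation_time"] >= t_start)
                   & (features["activation_time"] < t_end)]
    for (r, c), site in sub.groupby(["row", "col"]):
        act[int(r), int(c)] = site["activation_time"].min()
    finite = np.isfinite(act)
    ref = float(np.nanmin(act)) if finite.any() else np.nan
    return IsochroneMap(act - ref, ref, ~finite, pixel_pitch)


def isochrone_from_array(activation: np.ndarray, pixel_pitch: float = 0.25) -> IsochroneMap:
    """Wrap a dense activation-time array (NaN = unactivated)."""
    activation = np.asarray(activation, dtype=float)
    finite = np.isfinite(activation)
    ref = float(np.nanmin(activation)) if finite.any() else np.nan
    return IsochroneMap(activation - ref, ref, ~finite, pixel_pitch)


# ---------------------------------------------------------------------------
# conduction velocity


def estimate_cv(
    iso: IsochroneMap,
    neighborhood_px: int = 5,
    residual_threshold_ms: float = 4.0,
) -> dict:
    """Local-plane-fit conduction velocity field (mm/ms).

    For each activated site a plane T(x, y) is least-squares fitted to
    activation times in the surrounding ``neighborhood_px`` window; the
    velocity is grad T / |grad T|^2.  Sites with too few activated
    neighbours, a singular fit, or a residual RMS above threshold are
    excluded.  Returns the vector field, speed map, and a scalar
    summary (median speed over included sites).
    """
    if neighborhood_px < 3 or neighborhood_px % 2 == 0:
        raise ValueError("neighborhood_px must be odd and >= 3")
    T = iso.activation_time
    h0, w0 = T.shape
    half = neighborhood_px // 2
    pitch = iso.pixel_pitch
    vy = np.full((h0, w0), np.nan)
    vx = np.full((h0, w0), np.nan)
    speed = np.full((h0, w0), np.nan)
    for r in range(h0):
        for c in range(w0):
            if not np.isfinite(T[r, c]):
                continue
            r0, r1 = max(0, r - half), min(h0, r + half + 1)
            c0, c1 = max(0, c - half), min(w0, c + half + 1)
            patch = T[r0:r1, c0:c1]
            ok = np.isfinite(patch)
            if ok.sum() < 5:
                continue
            yy, xx = np.mgrid[r0:r1, c0:c1]
            ys = (yy[ok] - r) * pitch
            xs = (xx[ok] - c) * pitch
            design = np.column_stack([ys, xs, np.ones(ok.sum())])
            tvals = patch[ok]
            coef, res, rank, _ = np.linalg.lstsq(design, tvals, rcond=None)
            if rank < 3:
                continue  # collinear activated sites: singular fit
            rms = float(np.sqrt(np.mean((design @ coef - tvals) ** 2)))
            if rms > residual_threshold_ms:
                continue
            gy, gx = coef[0], coef[1]  # ms/mm slowness components
            g2 = gy * gy + gx * gx
            if g2 < 1e-12:
                continue
            vy[r, c] = gy / g2
            vx[r, c] = gx / g2
            speed[r, c] = 1.0 / np.sqrt(g2)
    included = np.isfinite(speed)
    summary = float(np.nanmedian(speed)) if included.any() else np.nan
    return {"vy": vy, "vx": vx, "speed": speed, "median_speed": summary,
            "n_sites": int(included.sum())}


# ---------------------------------------------------------------------------
# conduction block


def detect_conduction_block(
    iso: IsochroneMap,
    grad_threshold: float = 4.0,
    scar_mask: np.ndarray | None = None,
    alternans_map=None,
    nodal_distance_px: float = 3.0,
) -> dict:
    """Block lines: steep activation-time jumps and unactivated borders.

    An edge between adjacent activated sites with |dT| above
    ``grad_threshold`` (ms/px), or the boundary of an
    unactivated-but-analyzable region, is conduction block.  Edges
    adjacent to scar are labelled fixed; with an alternans map supplied,
    edges within ``nodal_distance_px`` of a nodal line are labelled
    functional.
    """
    T = iso.activation_time
    h0, w0 = T.shape
    block = np.zeros((h0, w0), dtype=bool)
    dv = np.abs(np.diff(T, axis=0))
    block[:-1, :] |= dv > grad_threshold
    block[1:, :] |= dv > grad_threshold
    dh = np.abs(np.diff(T, axis=1))
    block[:, :-1] |= dh > grad_threshold
    block[:, 1:] |= dh > grad_threshold
    # boundaries of unactivated-but-valid regions are functional block too
    un = iso.unactivated.copy()
    if scar_mask is not None:
        un &= ~scar_mask
    act = np.isfinite(T)
    border = np.zeros_like(block)
    border[:-1, :] |= un[:-1, :] & act[1:, :]
    border[1:, :] |= un[1:, :] & act[:-1, :]
    border[:, :-1] |= un[:, :-1] & act[:, 1:]
    border[:, 1:] |= un[:, 1:] & act[:, :-1]
    block |= border

    fixed = np.zeros_like(block)
    if scar_mask is not None and scar_mask.any():
        from scipy.ndimage import binary_dilation

        near_scar = binary_dilation(scar_mask, iterations=2)
        fixed = block & near_scar
    functional = block & ~fixed
    near_nodal = np.zeros_like(block)
    if alternans_map is not None and getattr(alternans_map, "nodal_lines", None):
        rr, cc = np.mgrid[0:h0, 0:w0]
        pts = np.vstack([np.asarray(line) for line in alternans_map.nodal_lines])
        for r, c in zip(*np.nonzero(functional)):
            d2 = (pts[:, 0] - r) ** 2 + (pts[:, 1] - c) ** 2
            if d2.min() <= nodal_distance_px**2:
                near_nodal[r, c] = True
    return {"block": block, "fixed": fixed, "functional": functional,
            "functional_near_nodal_line": near_nodal}


# ---------------------------------------------------------------------------
# phase and singularities


@dataclass
class PhaseMovie:
    """Per-frame, per-site instantaneous phase in (-pi, pi]."""

    phase: np.ndarray
    frame_interval: float
    method: str = "hilbert"
    valid: np.ndarray | None = None


def compute_phase(
    movie: OpticalMovie,
    method: str = "hilbert",
    delay_frames: int = 10,
    valid_mask: np.ndarray | None = None,
) -> PhaseMovie:
    """Instantaneous phase of each pixel's mean-subtracted trace.

    ``hilbert`` (default) uses the analytic signal; ``delay_embedding``
    uses atan2(s(t) - s(t - delay), s(t) - mean).  A periodically paced
    pixel sweeps 2 pi per cycle.  Constant pixels have no phase and are
    invalidated.  The window must contain at least two beats' worth of
    frames for the analytic signal to be meaningful.
    """
    data = movie.data
    n_t = data.shape[0]
    if n_t < 8:
        raise ValueError("window too short for phase analysis")
    centered = data - data.mean(axis=0)
    rng_ok = np.ptp(data, axis=0) > 1e-9
    if method == "hilbert":
        analytic = hilbert(centered, axis=0)
        phase = np.angle(analytic)
    elif method == "delay_embedding":
        delayed = np.empty_like(centered)
        delayed[delay_frames:] = centered[:-delay_frames]
        delayed[:delay_frames] = centered[0]
        phase = np.arctan2(centered - delayed, centered)
    else:
        raise ValueError(f"unknown phase method {method!r}")
    valid = rng_ok if valid_mask is None else (rng_ok & valid_mask)
    phase = np.where(valid[None, :, :], phase, np.nan)
    return PhaseMovie(phase, movie.frame_interval, method, valid)


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def singularity_charge_map(phase_frame: np.ndarray) -> np.ndarray:
    """Topological charge on each 2x2 plaquette: +1, -1, or 0.

    The closed-loop sum of wrapped phase differences around a plaquette
    is 0 for smooth fields and +/-2 pi around a phase singularity.
    NaN-touching plaquettes carry charge 0.
    """
    p = phase_frame
    d1 = _wrap(p[:-1, 1:] - p[:-1, :-1])
    d2 = _wrap(p[1:, 1:] - p[:-1, 1:])
    d3 = _wrap(p[1:, :-1] - p[1:, 1:])
    d4 = _wrap(p[:-1, :-1] - p[1:, :-1])
    loop = d1 + d2 + d3 + d4
    charge = np.zeros_like(loop)
    ok = np.isfinite(loop)
    charge[ok & (loop > np.pi)] = 1.0
    charge[ok & (loop < -np.pi)] = -1.0
    return charge


@dataclass
class SingularityTrack:
    """A tracked reentry pivot: (time, position, chirality) per frame."""

    frames: list = field(default_factory=list)  # (time_ms, (row, col), chirality)
    chirality: int = 0

    @property
    def lifespan(self) -> float:
        if len(self.frames) < 2:
            return 0.0
        return self.frames[-1][0] - self.frames[0][0]

    @property
    def positions(self) -> np.ndarray:
        return np.array([f[1] for f in self.frames], dtype=float)

    def rotations(self, period_ms: float) -> float:
        return self.lifespan / period_ms if period_ms > 0 else np.nan


def detect_singularities(
    phase: PhaseMovie,
    link_radius_px: float = 3.0,
    min_lifespan_frames: int = 2,
) -> list[SingularityTrack]:
    """Detect and track phase singularities across frames.

    Per frame, every charged 2x2 plaquette yields a singularity at the
    plaquette centre with chirality = sign of its winding.  Detections
    are linked frame-to-frame by nearest neighbour within
    ``link_radius_px`` (chirality must match); tracks shorter than
    ``min_lifespan_frames`` are discarded.
    """
    n_t = phase.phase.shape[0]
    active: list[SingularityTrack] = []
    done: list[SingularityTrack] = []
    for k in range(n_t):
        t = k * phase.frame_interval
        charge = singularity_charge_map(phase.phase[k])
        rows, cols = np.nonzero(charge)
        dets = [((r + 0.5, c + 0.5), int(charge[r, c])) for r, c in zip(rows, cols)]
        new_active: list[SingularityTrack] = []
        used = [False] * len(dets)
        for tr in active:
            (pr, pc) = tr.frames[-1][1]
            best, best_d2 = None, link_radius_px**2
            for i, ((r, c), chi) in enumerate(dets):
                if used[i] or chi != tr.chirality:
                    continue
                d2 = (r - pr) ** 2 + (c - pc) ** 2
                if d2 <= best_d2:
                    best, best_d2 = i, d2
            if best is not None:
                used[best] = True
                (r, c), chi = dets[best]
                tr.frames.append((t, (r, c), chi))
                new_active.append(tr)
            else:
                done.append(tr)
        for i, ((r, c), chi) in enumerate(dets):
            if not used[i]:
                tr = SingularityTrack(frames=[(t, (r, c), chi)], chirality=chi)
                new_active.append(tr)
        active = new_active
    done.extend(active)
    return [tr for tr in done if len(tr.frames) >= min_lifespan_frames]
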