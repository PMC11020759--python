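"""APD restitution map and a coupled-map cable.

Restitution — the dependence of an action potential's duration on the
preceding diastolic interval (DI) — is modelled by the classic
exponential map

    APD_{n+1} = apd_max - amplitude_a * exp(-DI_n / tau_restitution),

iterated with DI_n = PCL - APD_n under constant-cycle-length pacing.
When the map's slope at the fixed point exceeds one the period-1 rhythm
loses stability and APD alternans (a period-2 long-short pattern)
appears; the onset cycle length has a closed form (slope = 1), which the
detection pipeline is checked against.

The cable version paces site 0 and propagates activation with a
DI-dependent conduction velocity (CV restitution).  Propagation delays
desynchronise the local cycle length along the cable, which is the
standard mechanism by which spatially discordant alternans — opposite
alternation phase at the two ends separated by a node of zero
alternation — develops.  A site whose DI would fall below ``di_min``
fails to activate (conduction block / loss of 1:1 capture); distal
sites are not activated on that beat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RestitutionMap:
    """Exponential APD (and optional CV) restitution.

    Parameters
    ----------
    apd_max : float
        Asymptotic APD at long DI, ms.
    amplitude_a : float
        Restitution amplitude, ms; ``apd_max > amplitude_a > 0``.
    tau_restitution : float
        Restitution time constant, ms.
    cv_max : float
        Conduction velocity at long DI, mm/ms.
    cv_amplitude : float
        Fractional CV slowing at DI -> 0; 0 disables CV restitution.
    cv_tau : float
        CV restitution time constant, ms.
    di_min : float
        Shortest DI that still captures, ms.
    """

    apd_max: float = 200.0
    amplitude_a: float = 150.0
    tau_restitution: float = 30.0
    cv_max: float = 0.35
    cv_amplitude: float = 0.0
    cv_tau: float = 40.0
    di_min: float = 2.0

    def __post_init__(self) -> None:
        if not (self.apd_max > self.amplitude_a > 0):
            raise ValueError("require apd_max > amplitude_a > 0")
        if self.tau_restitution <= 0 or self.cv_tau <= 0:
            raise ValueError("time constants must be positive")
        if not (0 <= self.cv_amplitude < 1):
            raise ValueError("cv_amplitude must be in [0, 1)")

    def apd_next(self, di):
        di = np.asarray(di, dtype=float)
        return self.apd_max - self.amplitude_a * np.exp(-di / self.tau_restitution)

    def slope(self, di):
        """d(APD_{n+1})/d(DI_n) at a given DI."""
        di = np.asarray(di, dtype=float)
        return (self.amplitude_a / self.tau_restitution) * np.exp(-di / self.tau_restitution)

    def cv(self, di):
        di = np.asarray(di, dtype=float)
        return self.cv_max * (1.0 - self.cv_amplitude * np.exp(-di / self.cv_tau))

    def fixed_point(self, pcl: float) -> tuple[float, float]:
        """(APD*, DI*) of the period-1 orbit at a given PCL (bisection)."""
        lo, hi = 0.0, float(pcl)
        g = lambda apd: self.apd_next(pcl - apd) - apd
        if g(lo) < 0:  # map entirely below diagonal: APD* ~ 0 edge
            return 0.0, pcl
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if g(mid) > 0:
                lo = mid
            else:
                hi = mid
        apd = 0.5 * (lo + hi)
        return apd, pcl - apd

    def alternans_onset_pcl(self) -> float:
        """PCL at which the fixed point's slope equals one (closed form).

        Slope-1 condition: (a/tau) exp(-DI*/tau) = 1 gives
        DI* = tau ln(a/tau), APD* = apd_max - tau, hence
        PCL* = apd_max - tau + tau ln(a/tau).  Requires a > tau,
        otherwise the map is stable at every captured PCL.
        """
        a, tau = self.amplitude_a, self.tau_restitution
        if a <= tau:
            return math.nan
        return self.apd_max - tau + tau * math.log(a / tau)


def run_restitution_cable(
    rmap: RestitutionMap,
    pcl: float,
    n_beats: int,
    n_sites: int = 1,
    spacing_mm: float = 0.25,
    apd_initial: float | None = None,
    stim_times: np.ndarray | None = None,
) -> pd.DataFrame:
    """Iterate the restitution map along a paced cable.

    Site 0 is paced every ``pcl`` ms (or at explicit ``stim_times``).
    Returns a tidy frame with one row per (beat, site):
    ``beat, site, activation_time, di, apd, captured``.
    Blocked beats carry ``captured=False`` and NaN activation/di/apd.
    """
    if pcl <= 0:
        raise ValueError("pcl must be positive")
    if n_beats < 2:
        raise ValueError("need at least 2 beats")
    if n_sites < 1:
        raise ValueError("need at least 1 site")
    if stim_times is None:
        stim_times = np.arange(n_beats) * float(pcl)
    else:
        stim_times = np.asarray(stim_times, dtype=float)
        if np.any(np.diff(stim_times) <= 0):
            raise ValueError("stimulus times must be strictly increasing")
        n_beats = len(stim_times)

    if apd_initial is None:
        apd_initial = 0.6 * rmap.apd_max
    # repol[j]: end of the last action potential at site j
    repol = np.full(n_sites, -1e9)
    # seed history: pretend a beat ended apd_initial before the first stimulus
    repol[:] = stim_times[0] - max(pcl - apd_initial, rmap.di_min + 1.0)

    rows = []
    for n, t_stim in enumerate(stim_times):
        t = t_stim
        blocked = False
        for j in range(n_sites):
            if blocked:
                rows.append((n, j, np.nan, np.nan, np.nan, False))
                continue
            di = t - repol[j]
            if di < rmap.di_min:
                blocked = True
                rows.append((n, j, np.nan, np.nan, np.nan, False))
                continue
            apd = float(rmap.apd_next(di))
            rows.append((n, j, t, di, apd, True))
            repol[j] = t + apd
            if j + 1 < n_sites:
                t = t + spacing_mm / float(rmap.cv(di))
    return pd.DataFrame(
        rows, columns=["beat", "site", "activation_time", "di", "apd", "captured"]
    )


def run_independent_sites(
    rmap: RestitutionMap,
    pcl: float,
    n_beats: int,
    site_apd_shift: np.ndarray,
    apd_initial: float | None = None,
) -> pd.DataFrame:
    """Iterate the restitution map at heterogeneous, uncoupled sites.

    Each site carries its own additive shift of ``apd_max`` (mapped
    fields are never homogeneous; the study protocol reads alternans at
    the site of maximum magnitude, which presumes such spread).  All
    sites see the same stimulus train; a site whose DI falls below
    ``di_min`` simply skips that beat (local 2:1) without affecting its
    neighbours.  Same tidy schema as :func:`run_restitution_cable`.
    """
    if pcl <= 0:
        raise ValueError("pcl must be positive")
    shifts = np.asarray(site_apd_shift, dtype=float)
    n_sites = len(shifts)
    if apd_initial is None:
        apd_initial = 0.6 * rmap.apd_max
    repol = np.full(n_sites, -max(pcl - apd_initial, rmap.di_min + 1.0))
    rows = []
    for n in range(n_beats):
        t = n * pcl
        di = t - repol
        ok = di >= rmap.di_min
        apd = rmap.apd_next(di) + shifts
        apd = np.clip(apd, 1.0, None)
        for j in range(n_sites):
            if ok[j]:
                rows.append((n, j, t, di[j], apd[j], True))
            else:
                rows.append((n, j, np.nan, np.nan, np.nan, False))
        repol = np.where(ok, t + apd, repol)
    return pd.DataFrame(
        rows, columns=["beat", "site", "activation_time", "di", "apd", "captured"]
    )


def alternans_amplitude(result: pd.DataFrame, site: int | None = None,
                        discard: int | None = None) -> float:
    """Steady-state |APD_{n+1} - APD_n| at one site (default: last site).

    Discards the first ``discard`` beats (default: half) as transient.
    Returns 0 for a converged period-1 rhythm, NaN if the site lost
    capture in the analysis window.
    """
    if site is None:
        site = int(result["site"].max())
    sub = result[result["site"] == site].sort_values("beat")
    apd = sub["apd"].to_numpy()
    if discard is None:
        discard = len(apd) // 2
    tail = apd[discard:]
    if len(tail) < 2:
        raise ValueError("too few beats after discard")
    if np.any(~np.isfinite(tail)):
        return math.nan
    return float(np.mean(np.abs(np.diff(tail))))
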