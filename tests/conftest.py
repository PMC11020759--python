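"""Shared fixtures: small ground-truthed simulations, reused across tests."""

import warnings

import numpy as np
import pytest

from cardiomap.geometry import TissueGeometry, with_scar
from cardiomap.model import CellModelParams, PacingProtocol, simulate_tissue
from cardiomap.synth import discordant_alternans_recording

warnings.filterwarnings("ignore", message=".*Covariance.*")


@pytest.fixture(scope="session")
def planar_sim():
    """Planar-wave burst recording on a uniform strip (camera pitch)."""
    geo = TissueGeometry(height=16, width=60, pixel_pitch=0.25)
    proto = PacingProtocol(kind="burst", s1_count=5, s1s1=300.0, stim_site=(8, 2))
    return simulate_tissue(geo, CellModelParams(), proto, noise_snr_db=np.inf,
                           seed=7, record_tail_ms=250.0)


@pytest.fixture(scope="session")
def fine_strip_sim():
    """Single beat from rest on a refined-pitch strip (CV oracle checks).

    At rest the recovery gate is exactly 1 everywhere, so the first
    wavefront's speed admits the closed-form comparison.
    """
    geo = TissueGeometry(height=16, width=160, pixel_pitch=0.125)
    proto = PacingProtocol(kind="burst", s1_count=1, s1s1=350.0, stim_site=(8, 2))
    return simulate_tissue(geo, CellModelParams(), proto, noise_snr_db=np.inf,
                           seed=3, record_tail_ms=150.0)


@pytest.fixture(scope="session")
def scar_sim():
    """Paced recording with an infarct scar at 20 dB SNR."""
    geo = with_scar(24, 24, scar_center=(12.0, 7.0), scar_radius_px=4.0)
    proto = PacingProtocol(kind="burst", s1_count=8, s1s1=300.0, stim_site=(12, 20))
    sim = simulate_tissue(geo, CellModelParams(), proto, noise_snr_db=20.0,
                          seed=11, record_tail_ms=450.0)
    return geo, sim


@pytest.fixture(scope="session")
def discordant_rec():
    """Discordant-alternans strip with a blocking premature beat."""
    vm, truth = discordant_alternans_recording(noise_snr_db=20.0, seed=3,
                                               premature_fraction=0.8)
    return vm, truth
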