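"""In-memory containers for optical-mapping recordings.

An :class:`OpticalMovie` is one camera channel's T x H x W fluorescence
stack plus the acquisition metadata that makes the numbers interpretable
(frame interval, pixel pitch, channel identity, fluorescence polarity).
Metadata is mandatory: silent unit errors are the dominant failure mode
in this domain, so readers refuse files that omit it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

VALID_CHANNELS = ("vm", "cai")
VALID_POLARITIES = ("upright", "inverted")


class MovieError(ValueError):
    """Malformed movie data or metadata."""


class MetadataError(MovieError):
    """A required metadata field is missing or invalid."""


class InsufficientSitesError(RuntimeError):
    """Fewer analyzable sites than the study's minimum (default 25)."""


@dataclass
class OpticalMovie:
    """One channel's fluorescence stack.

    Attributes
    ----------
    data : ndarray, shape (T, H, W)
        Fluorescence values, float.
    frame_interval : float
        ms per frame (camera default 2.0).
    pixel_pitch : float
        mm per pixel (camera default 0.25).
    channel : {"vm", "cai"}
        Membrane-potential or intracellular-calcium channel.
    polarity : {"upright", "inverted"}
        "inverted" means depolarization *decreases* fluorescence (the
        RH-237 voltage-dye convention); preprocessing flips it.
    metadata : dict
        Free-form provenance record.
    """

    data: np.ndarray
    frame_interval: float = 2.0
    pixel_pitch: float = 0.25
    channel: str = "vm"
    polarity: str = "upright"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise MovieError(f"movie data must be T x H x W, got ndim={self.data.ndim}")
        if self.data.shape[0] < 2:
            raise MovieError(f"movie must have at least 2 frames, got {self.data.shape[0]}")
        if not self.frame_interval > 0:
            raise MetadataError("frame_interval must be > 0 ms")
        if not self.pixel_pitch > 0:
            raise MetadataError("pixel_pitch must be > 0 mm")
        if self.channel not in VALID_CHANNELS:
            raise MetadataError(f"channel must be one of {VALID_CHANNELS}, got {self.channel!r}")
        if self.polarity not in VALID_POLARITIES:
            raise MetadataError(
                f"polarity must be one of {VALID_POLARITIES}, got {self.polarity!r}"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def duration(self) -> float:
        """Total recording span in ms (first to last frame)."""
        return (self.n_frames - 1) * self.frame_interval

    def times(self) -> np.ndarray:
        """Frame timestamps in ms, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval

    def trace(self, row: int, col: int) -> np.ndarray:
        return self.data[:, row, col]

    def with_data(self, data: np.ndarray, **meta_updates) -> "OpticalMovie":
        """Copy with new data (and optionally new metadata fields)."""
        return replace(self, data=data, metadata=dict(self.metadata), **meta_updates)


@dataclass
class QualityMask:
    """Per-pixel analyzability mask derived from signal quality.

    ``valid`` marks pixels whose SNR meets ``snr_threshold``; infarct
    pixels emit only noise and fall below any sensible threshold, which
    is how the scar is excluded from analysis.
    """

    valid: np.ndarray
    snr_map: np.ndarray
    snr_threshold: float

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        self.snr_map = np.asarray(self.snr_map, dtype=np.float64)
        if self.valid.shape != self.snr_map.shape:
            raise MovieError("valid and snr_map shapes differ")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())
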