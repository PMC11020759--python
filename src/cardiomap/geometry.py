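"""Tissue geometry: imaging grid, infarct scar, and peri-infarct border zone.

The mapped field of view is a regular grid of camera pixels (default
100 x 100 at 0.25 mm pitch, i.e. a 2.5 cm x 2.5 cm window).  An infarct
scar is a connected region of unexcitable tissue that emits no optical
signal; the border zone is the rim of excitable tissue within a stated
distance of the scar, the substrate for ectopy and reentry anchoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class GeometryError(ValueError):
    """Invalid tissue geometry."""


@dataclass
class TissueGeometry:
    """Imaging grid with optional scar and border-zone masks.

    Parameters
    ----------
    height, width : int
        Grid size in pixels; at least 16 x 16.
    pixel_pitch : float
        Pixel edge length in mm (default 0.25).
    scar_mask : ndarray of bool, optional
        True inside the infarct (unexcitable, optically silent).
    border_zone_mask : ndarray of bool, optional
        True in the peri-infarct rim.  Derived from ``scar_mask`` by
        :func:`with_scar`; must be disjoint from the scar.
    """

    height: int = 100
    width: int = 100
    pixel_pitch: float = 0.25
    scar_mask: np.ndarray | None = None
    border_zone_mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise GeometryError(
                f"grid must be at least 16x16, got {self.height}x{self.width}"
            )
        if self.pixel_pitch <= 0:
            raise GeometryError("pixel_pitch must be positive")
        shape = (self.height, self.width)
        if self.scar_mask is None:
            self.scar_mask = np.zeros(shape, dtype=bool)
        else:
            self.scar_mask = np.asarray(self.scar_mask, dtype=bool)
        if self.border_zone_mask is None:
            self.border_zone_mask = np.zeros(shape, dtype=bool)
        else:
            self.border_zone_mask = np.asarray(self.border_zone_mask, dtype=bool)
        for name, mask in (("scar_mask", self.scar_mask),
                           ("border_zone_mask", self.border_zone_mask)):
            if mask.shape != shape:
                raise GeometryError(f"{name} shape {mask.shape} != grid {shape}")
        if np.any(self.scar_mask & self.border_zone_mask):
            raise GeometryError("scar_mask and border_zone_mask must be disjoint")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def excitable_mask(self) -> np.ndarray:
        return ~self.scar_mask

    def physical_extent_mm(self) -> tuple[float, float]:
        return (self.height * self.pixel_pitch, self.width * self.pixel_pitch)


def with_scar(
    height: int = 100,
    width: int = 100,
    pixel_pitch: float = 0.25,
    scar_center: tuple[float, float] | None = None,
    scar_radius_px: float = 0.0,
    border_width_mm: float = 1.0,
) -> TissueGeometry:
    """Build a geometry with a circular scar and its surrounding border zone.

    The border zone is every excitable pixel whose Euclidean distance to
    the scar is at most ``border_width_mm``.
    """
    shape = (height, width)
    scar = np.zeros(shape, dtype=bool)
    if scar_radius_px > 0:
        if scar_center is None:
            scar_center = (height / 2.0, width / 2.0)
        rr, cc = np.mgrid[0:height, 0:width]
        scar = (rr - scar_center[0]) ** 2 + (cc - scar_center[1]) ** 2 <= scar_radius_px**2
    border = np.zeros(shape, dtype=bool)
    if scar.any():
        dist_px = ndimage.distance_transform_edt(~scar)
        border = (~scar) & (dist_px * pixel_pitch <= border_width_mm)
    return TissueGeometry(
        height=height,
        width=width,
        pixel_pitch=pixel_pitch,
        scar_mask=scar,
        border_zone_mask=border,
    )
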