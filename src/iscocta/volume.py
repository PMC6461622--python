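"""Acquisition geometry and in-memory containers for OCT volume data.

An OCTA acquisition raster-scans the slow (y) axis over ``n_locations``
transversal positions and records ``n_repeats`` consecutive B-scan frames at
each position; every frame is ``n_alines`` depth profiles of ``n_depth``
samples.  The repeat dimension is what makes inter-frame flow statistics
possible: static tissue speckle is (nearly) identical across the repeats
while moving blood renews it.

Index convention, used everywhere in this package: ``(location j, repeat i,
fast-axis x, depth z)``, 0-based, with ``z = 0`` the shallowest sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Tuple

import numpy as np

from .errors import ConfigError, DataError

IntensityScale = Literal["linear", "log"]
Provenance = Literal["structural", "flow", "contrast"]


@dataclass(frozen=True)
class ScanProtocol:
    """Geometry of a repeat-frame raster acquisition.

    Parameters
    ----------
    n_alines:
        A-lines per B-scan along the fast (x) axis.
    n_locations:
        Transversal positions along the slow (y) axis.
    n_repeats:
        Consecutive frames captured at each location (the ``N`` of the
        inter-frame statistics; must be >= 2 so consecutive pairs exist).
    n_depth:
        Depth (z) samples per A-line.
    fov_x_mm, fov_y_mm, depth_mm:
        Physical extents of the scanned volume in millimetres.

    The defaults mirror a typical small-animal protocol: 256 A-lines,
    2,048 B-scans organised as 256 locations x 8 repeats, a 5.0 mm x 5.0 mm
    field of view and a 2.0 mm axial range.
    """

    n_alines: int = 256
    n_locations: int = 256
    n_repeats: int = 8
    n_depth: int = 1024
    fov_x_mm: float = 5.0
    fov_y_mm: float = 5.0
    depth_mm: float = 2.0

    def __post_init__(self) -> None:
        for name in ("n_alines", "n_locations", "n_repeats", "n_depth"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.n_repeats < 2:
            raise ConfigError(
                f"n_repeats must be >= 2 (consecutive frame pairs are required), got {self.n_repeats}"
            )
        for name in ("fov_x_mm", "fov_y_mm", "depth_mm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ConfigError(f"{name} must be a positive finite extent, got {v!r}")

    @property
    def n_bscans(self) -> int:
        """Total B-scan frames acquired: locations x repeats."""
        return self.n_locations * self.n_repeats

    @property
    def volume_shape(self) -> Tuple[int, int, int, int]:
        return (self.n_locations, self.n_repeats, self.n_alines, self.n_depth)

    @property
    def pixel_size_mm(self) -> Tuple[float, float]:
        """(dy, dx) en-face pixel pitch in mm."""
        return (self.fov_y_mm / self.n_locations, self.fov_x_mm / self.n_alines)


def validate_protocol(protocol: ScanProtocol, n_bscans: int) -> int:
    """Check a frame count against a protocol and return the location count.

    ``n_bscans`` must be divisible by ``protocol.n_repeats`` and the quotient
    must equal ``protocol.n_locations``; e.g. 2,048 B-scans at 8 repeats per
    location validate to 256 locations.
    """
    if n_bscans % protocol.n_repeats != 0:
        raise DataError(
            f"{n_bscans} B-scans are not divisible by n_repeats={protocol.n_repeats}"
        )
    n_locations = n_bscans // protocol.n_repeats
    if n_locations != protocol.n_locations:
        raise DataError(
            f"frame count implies {n_locations} locations but protocol declares "
            f"{protocol.n_locations}"
        )
    return n_locations


@dataclass
class OCTVolume:
    """A 4-D intensity volume ``(location, repeat, x, z)`` plus its protocol.

    ``intensity_scale`` records whether values are linear magnitude or
    log-compressed; the flow statistics are only defined on linear intensity,
    so the tag forces the caller to convert explicitly rather than silently.
    """

    protocol: ScanProtocol
    data: np.ndarray
    intensity_scale: IntensityScale = "linear"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise DataError(f"volume data must be 4-D, got ndim={self.data.ndim}")
        if self.data.shape != self.protocol.volume_shape:
            raise DataError(
                f"data shape {self.data.shape} does not match protocol shape "
                f"{self.protocol.volume_shape}"
            )
        if self.intensity_scale not in ("linear", "log"):
            raise ConfigError(f"unknown intensity_scale {self.intensity_scale!r}")
        if self.intensity_scale == "linear" and np.any(self.data < 0):
            raise DataError("linear-scale volume contains negative intensities")

    @property
    def shape(self) -> Tuple[int, int, int, int]:
        return self.data.shape


@dataclass
class EnFaceImage:
    """A 2-D top-down (locations x A-lines) projection of a volume."""

    pixels: np.ndarray
    pixel_size_mm: Tuple[float, float] = (1.0, 1.0)
    provenance: Provenance = "flow"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise DataError(f"en-face image must be 2-D, got ndim={self.pixels.ndim}")
        if np.any(self.pixels < 0):
            raise DataError("en-face image contains negative values")
        if self.provenance not in ("structural", "flow", "contrast"):
            raise ConfigError(f"unknown provenance {self.provenance!r}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass
class VesselMask:
    """Binary vessel map: 1 marks vessel pixels, 0 marks noise/background."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise DataError(f"vessel mask must be 2-D, got ndim={arr.ndim}")
        if arr.dtype != bool and not np.isin(arr, (0, 1)).all():
            raise DataError("vessel mask values must be 0 or 1")
        self.pixels = arr.astype(bool)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    @property
    def vessel_pixels(self) -> int:
        return int(self.pixels.sum())

    @property
    def total_pixels(self) -> int:
        return int(self.pixels.size)
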