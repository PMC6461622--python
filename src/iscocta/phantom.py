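"""Synthetic repeat-frame speckle phantoms with ground-truth vessels.

The phantom emulates the physical premise that inter-frame flow imaging
exploits: static tissue speckle is correlated across the N repeated frames
at a location, while intravascular speckle renews between frames.

Speckle model — fully developed speckle: each voxel has a circular complex
Gaussian amplitude ``g`` with unit mean square, so its noiseless intensity
``|g|**2 * reflectivity`` is exponentially distributed with the stated mean.
Static voxels reuse one amplitude draw for all N repeats; vessel voxels
renew it between consecutive frames by the autoregressive update

    g[i+1] = sqrt(1 - rho) * g[i] + sqrt(rho) * g_new

with ``g_new`` fresh per frame, so ``rho`` in [0, 1] is the fraction of
speckle power renewed per frame (rho = 0: frozen; rho = 1: fully
decorrelated).  Additive Gaussian detector noise (clipped at zero) is drawn
fresh per frame everywhere.  All randomness flows from one integer seed
through numpy's PCG64 generator, so volumes are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .errors import ConfigError
from .volume import OCTVolume, ScanProtocol

# (start, end, radius): segment axis endpoints in voxel coordinates
# (location j, x, z), radius in voxels.
VesselSegment = Tuple[Tuple[float, float, float], Tuple[float, float, float], float]


@dataclass
class PhantomSpec:
    """Recipe for a synthetic repeat-frame volume with known vessels.

    tissue_reflectivity / vessel_reflectivity are mean linear intensities;
    noise_sigma is the standard deviation of additive intensity noise, so
    SNR ~= tissue_reflectivity / noise_sigma.
    """

    protocol: ScanProtocol
    vessels: List[VesselSegment] = field(default_factory=list)
    decorrelation: float = 0.8
    tissue_reflectivity: float = 1.0
    vessel_reflectivity: float = 1.0
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.decorrelation <= 1.0:
            raise ConfigError(f"decorrelation must be in [0, 1], got {self.decorrelation}")
        if self.tissue_reflectivity <= 0 or self.vessel_reflectivity <= 0:
            raise ConfigError("reflectivities must be positive")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be nonnegative")
        shape = np.array(
            [self.protocol.n_locations, self.protocol.n_alines, self.protocol.n_depth]
        )
        for p0, p1, r in self.vessels:
            if r < 1:
                raise ConfigError(f"vessel radius must be >= 1 voxel, got {r}")
            for p in (p0, p1):
                if np.any(np.asarray(p) < 0) or np.any(np.asarray(p) > shape - 1):
                    raise ConfigError(f"vessel endpoint {p} outside volume of shape {tuple(shape)}")


@dataclass
class PhantomTruth:
    """Ground truth for a rendered phantom.

    ``vessel_voxels`` is the 3-D binary vessel map ``(location, x, z)``;
    ``enface_mask`` marks columns containing any vessel voxel; and
    ``enface_vessel_fraction`` is the mean of that mask — the true vessel
    area density of the en-face view.
    """

    vessel_voxels: np.ndarray
    enface_mask: np.ndarray
    enface_vessel_fraction: float


def _segment_distance(
    points: np.ndarray, p0: np.ndarray, p1: np.ndarray
) -> np.ndarray:
    """Euclidean distance from each point (..., 3) to the segment p0-p1."""
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        return np.linalg.norm(points - p0, axis=-1)
    t = np.clip(((points - p0) @ d) / L2, 0.0, 1.0)
    nearest = p0 + t[..., None] * d
    return np.linalg.norm(points - nearest, axis=-1)


def rasterize_vessels(spec: PhantomSpec) -> PhantomTruth:
    """Voxelise the tube segments: a voxel is vessel iff its centre lies
    within a segment's radius (Euclidean distance in voxel units)."""
    p = spec.protocol
    shape = (p.n_locations, p.n_alines, p.n_depth)
    vessel = np.zeros(shape, dtype=bool)
    jj, xx, zz = np.meshgrid(
        np.arange(p.n_locations), np.arange(p.n_alines), np.arange(p.n_depth),
        indexing="ij",
    )
    points = np.stack([jj, xx, zz], axis=-1).astype(float)
    for p0, p1, r in spec.vessels:
        dist = _segment_distance(points, np.asarray(p0, float), np.asarray(p1, float))
        vessel |= dist <= r
    enface = vessel.any(axis=2)
    return PhantomTruth(
        vessel_voxels=vessel,
        enface_mask=enface,
        enface_vessel_fraction=float(enface.mean()),
    )


def _complex_gaussian(rng: np.random.Generator, shape: Tuple[int, ...]) -> np.ndarray:
    """Circular complex Gaussian with E|g|^2 = 1."""
    return (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2.0)


def render_volume(spec: PhantomSpec) -> Tuple[OCTVolume, PhantomTruth]:
    """Render the repeat-frame speckle volume described by ``spec``.

    Returns the linear-intensity :class:`OCTVolume` ``(location, repeat, x,
    z)`` and the matching :class:`PhantomTruth`.  Same spec (including seed)
    gives bit-identical output.
    """
    truth = rasterize_vessels(spec)
    p = spec.protocol
    rng = np.random.default_rng(spec.seed)
    vol_shape = (p.n_locations, p.n_alines, p.n_depth)
    rho = spec.decorrelation
    vessel = truth.vessel_voxels

    reflectivity = np.where(vessel, spec.vessel_reflectivity, spec.tissue_reflectivity)
    data = np.empty((p.n_locations, p.n_repeats, p.n_alines, p.n_depth))

    g = _complex_gaussian(rng, vol_shape)
    keep, renew = np.sqrt(1.0 - rho), np.sqrt(rho)
    for i in range(p.n_repeats):
        if i > 0:
            g_new = _complex_gaussian(rng, vol_shape)
            # static voxels keep their draw; vessel voxels renew AR(1)-style
            g = np.where(vessel, keep * g + renew * g_new, g)
        intensity = np.abs(g) ** 2 * reflectivity
        if spec.noise_sigma > 0:
            intensity = intensity + rng.normal(0.0, spec.noise_sigma, vol_shape)
        data[:, i] = np.clip(intensity, 0.0, None)

    return OCTVolume(protocol=p, data=data, intensity_scale="linear"), truth


REFERENCE_SEED = 20260

# Fixed reference geometry: 64 locations x 64 A-lines x 64 depth samples,
# 4 repeats; three straight tubes of radius 2/3/4 voxels spanning the fast
# axis at distinct slow-axis rows and depths (one with a gentle axial slope).
_REFERENCE_VESSELS: List[VesselSegment] = [
    ((12.0, 0.0, 20.0), (12.0, 63.0, 20.0), 2.0),
    ((32.0, 0.0, 30.0), (32.0, 63.0, 40.0), 3.0),
    ((50.0, 0.0, 45.0), (50.0, 63.0, 45.0), 4.0),
]


def reference_spec(seed: int = REFERENCE_SEED) -> PhantomSpec:
    """The fixed reference phantom recipe used throughout the test surface.

    64 x 64 x 64 voxels, 4 repeats per location, three vessels of varied
    radius, decorrelation 0.8 and SNR ~ 10 (noise_sigma = 0.1 on unit mean
    tissue intensity).
    """
    protocol = ScanProtocol(
        n_alines=64,
        n_locations=64,
        n_repeats=4,
        n_depth=64,
        fov_x_mm=1.25,
        fov_y_mm=1.25,
        depth_mm=0.5,
    )
    return PhantomSpec(
        protocol=protocol,
        vessels=list(_REFERENCE_VESSELS),
        decorrelation=0.8,
        tissue_reflectivity=1.0,
        vessel_reflectivity=1.0,
        noise_sigma=0.1,
        seed=seed,
    )


def reference_phantom(seed: int = REFERENCE_SEED) -> Tuple[OCTVolume, PhantomTruth]:
    """Render the fixed reference phantom (deterministic for a given seed)."""
    return render_volume(reference_spec(seed))
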