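"""Inter-frame speckle contrast flow imaging.

Given the ``N`` consecutive B-scan frames ``I(x, y_i, z)`` repeated at one
transversal location, three per-pixel images are formed:

* mean image       ``I_s = (1/N) * sum_i I_i``
* contrast image   ``K_s = (1/(N-1)) * sum_{i=1}^{N-1} |I_{i+1} - I_i| / (I_{i+1} + I_i)``
* flow image       ``I_flow = I_s * K_s``

``K_s`` is a normalised first-difference statistic over consecutive frame
pairs: each term lies in [0, 1] for nonnegative intensities, vanishes where
speckle is static and grows with frame-to-frame decorrelation (blood flow).
Masking the mean image with it suppresses static tissue while preserving
flow signal.  All three are computed on linear intensity — the ratio in
``K_s`` is invariant under a global intensity scale there, and
log-compressed data would break the [0, 1] bound.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .errors import DataError
from .volume import OCTVolume


def _validate_stack(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise DataError(f"frame stack must be 3-D (repeat, x, z), got ndim={frames.ndim}")
    if frames.shape[0] < 2:
        raise DataError(f"need N >= 2 repeated frames, got N={frames.shape[0]}")
    if np.any(frames < 0):
        raise DataError("frame stack contains negative intensities")
    return frames


def mean_image(frames: np.ndarray) -> np.ndarray:
    """Pixelwise arithmetic mean over the N repeated frames."""
    frames = _validate_stack(frames)
    return frames.mean(axis=0)


def speckle_contrast(frames: np.ndarray, epsilon: float = 0.0) -> np.ndarray:
    """Per-pixel inter-frame speckle contrast ``K_s`` over consecutive pairs.

    Parameters
    ----------
    frames:
        Nonnegative linear-intensity stack ``(repeat, x, z)``, N >= 2, with
        repeats in acquisition order (the statistic uses consecutive pairs).
    epsilon:
        Optional nonnegative denominator regulariser absorbing detector
        noise at dark pixels; default 0.  With epsilon = 0 a pair that is
        zero in both frames contributes 0 (the 0/0 -> 0 convention: a pixel
        dark in both frames carries no flow evidence).

    Returns
    -------
    2-D array in [0, 1].
    """
    frames = _validate_stack(frames)
    if epsilon < 0:
        raise DataError(f"epsilon must be nonnegative, got {epsilon}")
    num = np.abs(np.diff(frames, axis=0))
    den = frames[1:] + frames[:-1] + epsilon
    terms = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return terms.mean(axis=0)


def flow_image(mean: np.ndarray, contrast: np.ndarray) -> np.ndarray:
    """Mask the mean image with the contrast image (pixelwise product)."""
    mean = np.asarray(mean, dtype=float)
    contrast = np.asarray(contrast, dtype=float)
    if mean.shape != contrast.shape:
        raise DataError(
            f"mean {mean.shape} and contrast {contrast.shape} shapes differ"
        )
    return mean * contrast


def register_stack(frames: np.ndarray) -> np.ndarray:
    """Rigidly align repeats to the first frame by phase cross-correlation.

    Subpixel-free integer x-z shifts; a guard against bulk motion between
    repeats.  Off by default in the pipeline (acquisitions with good
    fixation need none).
    """
    frames = _validate_stack(frames)
    out = frames.copy()
    ref = frames[0]
    for i in range(1, frames.shape[0]):
        shift, _, _ = phase_cross_correlation(ref, frames[i], upsample_factor=1)
        if np.any(shift != 0):
            out[i] = ndimage.shift(frames[i], shift, order=1, mode="nearest")
            np.clip(out[i], 0, None, out=out[i])
    return out


def process_stack(
    frames: np.ndarray, epsilon: float = 0.0, register: str = "none"
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean, contrast and flow images for one location's repeat stack."""
    if register == "rigid":
        frames = register_stack(frames)
    elif register != "none":
        raise DataError(f"unknown registration mode {register!r}")
    m = mean_image(frames)
    k = speckle_contrast(frames, epsilon=epsilon)
    return m, k, flow_image(m, k)


def process_volume(
    volume: OCTVolume,
    epsilon: float = 0.0,
    register: str = "none",
    crop_top: int = 0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply the three-step flow algorithm at every transversal location.

    Parameters
    ----------
    volume:
        Linear-intensity repeat-frame volume ``(location, repeat, x, z)``.
        Log-scaled volumes are rejected; convert explicitly first.
    epsilon:
        Denominator regulariser passed to :func:`speckle_contrast`.
    register:
        ``none`` (default) or ``rigid`` inter-frame x-z registration.
    crop_top:
        Number of shallow depth samples to drop before processing (zero-delay
        / DC artifact exclusion); default 0.

    Returns
    -------
    (mean_volume, contrast_volume, flow_volume), each shaped
    ``(n_locations, n_alines, n_depth - crop_top)``.
    """
    if volume.intensity_scale != "linear":
        raise DataError(
            "flow statistics are defined on linear intensity; convert the "
            f"{volume.intensity_scale}-scaled volume explicitly first"
        )
    if not 0 <= crop_top < volume.protocol.n_depth:
        raise DataError(f"crop_top={crop_top} out of range for n_depth={volume.protocol.n_depth}")
    data = volume.data[..., crop_top:]
    n_loc, _, n_x, n_z = data.shape
    mean_vol = np.empty((n_loc, n_x, n_z))
    contrast_vol = np.empty((n_loc, n_x, n_z))
    flow_vol = np.empty((n_loc, n_x, n_z))
    for j in range(n_loc):
        m, k, f = process_stack(data[j], epsilon=epsilon, register=register)
        mean_vol[j], contrast_vol[j], flow_vol[j] = m, k, f
    return mean_vol, contrast_vol, flow_vol
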