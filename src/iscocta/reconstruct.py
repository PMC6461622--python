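"""Spectral-domain OCT reconstruction: interferogram lines to depth profiles.

A spectrometer-based FD-OCT system records, per A-line, a real interferogram
sampled over spectral pixels.  Reconstruction follows the standard chain:
background (DC / source spectrum) subtraction, resampling to a uniform
wavenumber (k) grid, optional polynomial dispersion compensation, and a
Fourier transform along the spectral axis whose magnitude gives the
structural depth profile.

Dispersion is modelled as the common minimal two-coefficient polynomial
phase ``exp(i * (a2 * kbar**2 + a3 * kbar**3))`` on the centred normalised
wavenumber ``kbar`` in [-1, 1]; compensation multiplies each line by the
conjugate of that phase.  Using the normalised basis keeps the coefficient
magnitudes independent of the instrument's absolute k range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.signal.windows import hann

from .errors import ConfigError, DataError


@dataclass
class SpectralFrame:
    """Raw spectral B-scan: ``spectra`` is (n_alines, n_spectral_pixels).

    ``background`` is the source-spectrum/DC term (one value per spectral
    pixel); when absent it can be estimated as the mean spectrum over
    A-lines.  ``k_map`` maps pixel index to wavenumber; when absent the
    sampling is assumed already linear in k.  Complex-valued spectra are
    permitted internally (after dispersion compensation).
    """

    spectra: np.ndarray
    background: Optional[np.ndarray] = None
    k_map: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra)
        if self.spectra.ndim != 2 or self.spectra.shape[1] < 2:
            raise DataError(
                f"spectra must be 2-D with >= 2 spectral pixels, got shape {self.spectra.shape}"
            )
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=float)
            if self.background.shape != (self.spectra.shape[1],):
                raise DataError(
                    f"background length {self.background.shape} does not match "
                    f"{self.spectra.shape[1]} spectral pixels"
                )
        if self.k_map is not None:
            self.k_map = np.asarray(self.k_map, dtype=float)
            if self.k_map.shape != (self.spectra.shape[1],):
                raise DataError("k_map length does not match spectral pixel count")
            d = np.diff(self.k_map)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise DataError("k_map must be strictly monotone")

    @property
    def n_alines(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_spectral_pixels(self) -> int:
        return self.spectra.shape[1]


@dataclass(frozen=True)
class DispersionModel:
    """Polynomial dispersion phase coefficients; (0, 0) is the identity."""

    a2: float = 0.0
    a3: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a2) and np.isfinite(self.a3)):
            raise ConfigError("dispersion coefficients must be finite")

    def phase(self, kbar: np.ndarray) -> np.ndarray:
        """Dispersion phase (radians) on the centred normalised wavenumber."""
        return self.a2 * kbar**2 + self.a3 * kbar**3


def _centered_kbar(n: int) -> np.ndarray:
    """Centred, normalised wavenumber grid spanning [-1, 1] over n pixels."""
    return np.linspace(-1.0, 1.0, n)


def subtract_background(frame: SpectralFrame) -> SpectralFrame:
    """Remove the background spectrum from every A-line.

    Uses ``frame.background`` when present; otherwise the per-pixel mean over
    A-lines (in which case the result's column means are exactly zero).
    """
    bg = frame.background
    if bg is None:
        bg = frame.spectra.mean(axis=0)
    return SpectralFrame(
        spectra=frame.spectra - bg[None, :],
        background=None,
        k_map=frame.k_map,
    )


def resample_to_k(frame: SpectralFrame) -> SpectralFrame:
    """Interpolate spectra onto a uniform wavenumber grid (same length).

    Linear interpolation between the sampled wavenumbers; the output frame
    carries the uniform grid as its ``k_map``.
    """
    if frame.k_map is None:
        raise DataError("resample_to_k requires a k_map")
    k = frame.k_map
    if k[0] > k[-1]:  # normalise to ascending for interpolation
        k = k[::-1]
        spectra = frame.spectra[:, ::-1]
    else:
        spectra = frame.spectra
    k_uniform = np.linspace(k[0], k[-1], frame.n_spectral_pixels)
    out = np.empty_like(spectra, dtype=float)
    for i in range(spectra.shape[0]):
        out[i] = np.interp(k_uniform, k, spectra[i].real)
    return SpectralFrame(spectra=out, background=frame.background, k_map=k_uniform)


def compensate_dispersion(frame: SpectralFrame, model: DispersionModel) -> SpectralFrame:
    """Multiply each line by the conjugate of the model's dispersion phase.

    The identity model returns the input unchanged (bit-exact).  Output
    spectra are complex whenever the model is non-trivial.
    """
    if model.a2 == 0.0 and model.a3 == 0.0:
        return frame
    kbar = _centered_kbar(frame.n_spectral_pixels)
    corr = np.exp(-1j * model.phase(kbar))
    return SpectralFrame(
        spectra=frame.spectra * corr[None, :],
        background=frame.background,
        k_map=frame.k_map,
    )


def apply_window(frame: SpectralFrame, window: str = "none") -> SpectralFrame:
    """Optionally apodise each line (``none`` or ``hann``) before transform."""
    if window == "none":
        return frame
    if window != "hann":
        raise ConfigError(f"unknown window {window!r}; use 'none' or 'hann'")
    w = hann(frame.n_spectral_pixels, sym=False)
    return SpectralFrame(
        spectra=frame.spectra * w[None, :],
        background=frame.background,
        k_map=frame.k_map,
    )


def reconstruct_bscan(frame: SpectralFrame) -> np.ndarray:
    """Fourier-transform spectra to depth; returns (n_alines, n_depth) >= 0.

    Per A-line the magnitude of the DFT over spectral pixels is taken and the
    single-sided half kept (``n_depth = n_spectral_pixels // 2``), giving a
    linear-intensity structural image.  Requires an even pixel count.
    """
    m = frame.n_spectral_pixels
    if m % 2 != 0:
        raise DataError(f"n_spectral_pixels must be even, got {m}")
    depth = np.fft.fft(frame.spectra, axis=1)[:, : m // 2]
    return np.abs(depth)


def reconstruct(
    frame: SpectralFrame,
    model: Optional[DispersionModel] = None,
    window: str = "none",
) -> np.ndarray:
    """Full chain: background -> k-resampling -> dispersion -> transform."""
    f = subtract_background(frame)
    if f.k_map is not None:
        f = resample_to_k(f)
    if model is not None:
        f = compensate_dispersion(f, model)
    f = apply_window(f, window)
    return reconstruct_bscan(f)


def peak_fwhm(profile: np.ndarray) -> float:
    """Full width at half maximum of the dominant peak, in samples.

    Linear interpolation of the half-maximum crossings around the argmax;
    used to verify that dispersion compensation sharpens a reflector.
    """
    profile = np.asarray(profile, dtype=float)
    i = int(np.argmax(profile))
    half = profile[i] / 2.0
    lo = float(i)
    for j in range(i, 0, -1):
        if profile[j - 1] < half:
            lo = (j - 1) + (half - profile[j - 1]) / (profile[j] - profile[j - 1])
            break
    else:
        lo = 0.0
    hi = float(i)
    for j in range(i, len(profile) - 1):
        if profile[j + 1] < half:
            hi = j + (profile[j] - half) / (profile[j] - profile[j + 1])
            break
    else:
        hi = float(len(profile) - 1)
    return hi - lo
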