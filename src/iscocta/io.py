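"""Readers and writers for volumes and en-face images.

Two on-disk dialects are supported:

* multi-page TIFF — one grayscale page per B-scan frame, pages ordered
  location-major / repeat-minor (all repeats of location 0, then location 1,
  ...), matching the acquisition order of a repeat-frame raster;
* flat raw binary — C-order ``(location, repeat, x, z)`` array.

Either dialect is accompanied by a YAML sidecar (``<file>.yaml``) carrying
every protocol field, the intensity scale and the element dtype, so a volume
is never read by guessing its layout.
"""

from __future__ import annotations

import os
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile
import yaml

from .errors import DataError
from .volume import EnFaceImage, OCTVolume, ScanProtocol, VesselMask, validate_protocol

PathLike = Union[str, os.PathLike]

_PROTOCOL_FIELDS = (
    "n_alines",
    "n_locations",
    "n_repeats",
    "n_depth",
    "fov_x_mm",
    "fov_y_mm",
    "depth_mm",
)


def sidecar_path(path: PathLike) -> Path:
    return Path(str(path) + ".yaml")


def write_sidecar(path: PathLike, volume: OCTVolume) -> Path:
    """Write the YAML sidecar describing ``volume`` next to ``path``."""
    meta = {f: getattr(volume.protocol, f) for f in _PROTOCOL_FIELDS}
    meta["intensity_scale"] = volume.intensity_scale
    meta["dtype"] = str(volume.data.dtype)
    sc = sidecar_path(path)
    sc.write_text(yaml.safe_dump(meta, sort_keys=False))
    return sc


def read_sidecar(path: PathLike) -> dict:
    sc = sidecar_path(path)
    if not sc.exists():
        raise DataError(f"sidecar metadata file not found: {sc}")
    meta = yaml.safe_load(sc.read_text())
    if not isinstance(meta, dict):
        raise DataError(f"malformed sidecar: {sc}")
    return meta


def protocol_from_sidecar(meta: dict) -> ScanProtocol:
    missing = [f for f in _PROTOCOL_FIELDS if f not in meta]
    if missing:
        raise DataError(f"sidecar is missing protocol fields: {missing}")
    return ScanProtocol(**{f: meta[f] for f in _PROTOCOL_FIELDS})


def _is_tiff(path: Path) -> bool:
    return path.suffix.lower() in (".tif", ".tiff")


def read_volume(path: PathLike, protocol: Optional[ScanProtocol] = None) -> OCTVolume:
    """Read an :class:`OCTVolume` from a TIFF stack or raw binary file.

    If ``protocol`` is omitted it is taken from the sidecar, which must then
    exist.  The page/frame count must match the protocol exactly; a
    mismatch raises :class:`DataError` rather than guessing a layout.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input volume not found: {path}")

    meta: dict = {}
    if protocol is None or not _is_tiff(path):
        meta = read_sidecar(path)
    if protocol is None:
        protocol = protocol_from_sidecar(meta)
    scale = meta.get("intensity_scale", "linear")

    if _is_tiff(path):
        pages = tifffile.imread(path)
        if pages.ndim == 2:  # single page
            pages = pages[None]
        if pages.ndim != 3:
            raise DataError(f"TIFF stack must hold 2-D grayscale pages, got ndim={pages.ndim}")
        n_pages = pages.shape[0]
        validate_protocol(protocol, n_pages)
        if pages.shape[1:] != (protocol.n_alines, protocol.n_depth):
            raise DataError(
                f"TIFF page shape {pages.shape[1:]} does not match protocol "
                f"(n_alines={protocol.n_alines}, n_depth={protocol.n_depth})"
            )
        data = pages.reshape(protocol.volume_shape)
    else:
        dtype = np.dtype(meta.get("dtype", "float32"))
        flat = np.fromfile(path, dtype=dtype)
        expected = int(np.prod(protocol.volume_shape))
        if flat.size != expected:
            raise DataError(
                f"raw file holds {flat.size} elements, protocol expects {expected}"
            )
        data = flat.reshape(protocol.volume_shape)

    return OCTVolume(protocol=protocol, data=data, intensity_scale=scale)


def write_volume(volume: OCTVolume, path: PathLike) -> None:
    """Write ``volume`` (TIFF stack or raw binary, by extension) plus sidecar.

    Round-trips are bit-exact for integer data and exact at storage precision
    for floats (float32/float64 pages are written untouched).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_tiff(path):
        p = volume.protocol
        pages = volume.data.reshape(p.n_bscans, p.n_alines, p.n_depth)
        tifffile.imwrite(path, pages, photometric="minisblack")
    else:
        volume.data.tofile(path)
    write_sidecar(path, volume)


def write_bscan_stack(stack: np.ndarray, path: PathLike) -> None:
    """Write a plain 3-D ``(frame, x, z)`` stack as a multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack), photometric="minisblack")


def write_enface(image: EnFaceImage, path: PathLike) -> None:
    """Export an en-face image as TIFF (float) or PNG (8-bit, max-scaled)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".png":
        peak = float(image.pixels.max())
        scaled = image.pixels / peak if peak > 0 else image.pixels
        import imageio.v3 as iio

        iio.imwrite(path, (np.clip(scaled, 0, 1) * 255).astype(np.uint8))
    else:
        tifffile.imwrite(path, image.pixels.astype(np.float32))


def write_mask(mask: VesselMask, path: PathLike) -> None:
    """Export a binary vessel mask as a 0/255 PNG (or TIFF)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = (mask.pixels.astype(np.uint8)) * 255
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, img)
    else:
        tifffile.imwrite(path, img)
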