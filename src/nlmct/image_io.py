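"""Grayscale image reading and writing (PNG, TIFF, read-only DICOM).

Intensities are never rescaled on read: an 8-bit file yields floats in
0–255, a 16-bit file its raw stored values, a DICOM slice its stored pixel
values.  Color inputs are rejected — the filter is defined on scalar
intensity images.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["read_image", "write_image"]

_PNG = {".png"}
_TIFF = {".tif", ".tiff"}
_DICOM = {".dcm", ".dicom"}


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8/16-bit grayscale PNG or TIFF (or float TIFF), or a
    single-frame grayscale DICOM, as a float64 array with values preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    if suffix in _PNG:
        arr = iio.imread(path)
    elif suffix in _TIFF:
        arr = tifffile.imread(path)
    elif suffix in _DICOM:
        arr = _read_dicom(path)
    else:
        raise ValueError(f"unsupported image format {suffix!r}: expected PNG, TIFF or DICOM")
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] in (2, 3, 4):
        raise ValueError(f"grayscale required: {path} has {arr.shape[2]} channels")
    if arr.ndim != 2:
        raise ValueError(f"expected a single 2D grayscale frame, got shape {arr.shape}")
    return arr.astype(np.float64)


def _read_dicom(path: Path) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - depends on install extras
        raise RuntimeError(
            "DICOM input requires the optional pydicom dependency "
            "(pip install nlmct[dicom]); PNG and TIFF input work without it"
        ) from exc
    ds = pydicom.dcmread(str(path))
    return np.asarray(ds.pixel_array)


def write_image(img: np.ndarray, path: str | Path, depth: int | str = 8) -> None:
    """Write *img* at the requested depth.

    ``depth=8``/``16``: values clipped to the type range and rounded
    half-to-even, written as PNG or TIFF by file suffix.  ``depth="float"``:
    exact float64 values, TIFF only.
    """
    path = Path(path)
    img = np.asarray(img, dtype=np.float64)
    suffix = path.suffix.lower()
    if depth == "float":
        if suffix not in _TIFF:
            raise ValueError("float output requires a .tif/.tiff path")
        tifffile.imwrite(path, img)
        return
    if depth == 8:
        data = np.rint(np.clip(img, 0, 255)).astype(np.uint8)
    elif depth == 16:
        data = np.rint(np.clip(img, 0, 65535)).astype(np.uint16)
    else:
        raise ValueError(f"depth must be 8, 16 or 'float', got {depth!r}")
    if suffix in _PNG:
        iio.imwrite(path, data)
    elif suffix in _TIFF:
        tifffile.imwrite(path, data)
    else:
        raise ValueError(f"unsupported output format {suffix!r}: expected PNG or TIFF")
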