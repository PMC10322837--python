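"""Image and table IO: TIFF/PNG readers, 16-bit mask/label writers."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import InvalidInputError

__all__ = ["read_image", "write_image", "write_label_map", "write_mask"]

_TIFF_SUFFIXES = {".tif", ".tiff"}


def read_image(path) -> np.ndarray:
    """Read a TIFF or PNG image as a numpy array (grayscale 2-D or RGB 3-D).

    RGBA inputs are reduced to RGB; 8- and 16-bit integer images are
    returned in their native dtype.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.ndim not in (2, 3):
        raise InvalidInputError(f"{path}: unsupported image shape {arr.shape}")
    return arr


def write_image(path, img: np.ndarray) -> None:
    """Write an image as TIFF (preferred) or PNG based on the suffix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = np.asarray(img)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        tifffile.imwrite(path, img)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, img)


def write_label_map(path, labels: np.ndarray) -> None:
    """Write a label map as 16-bit single-channel TIFF."""
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise InvalidInputError("more than 65535 objects; cannot store as uint16")
    write_image(path, labels.astype(np.uint16))


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as 16-bit TIFF (0 background, 65535 foreground)."""
    mask = np.asarray(mask, dtype=bool)
    write_image(path, np.where(mask, np.uint16(65535), np.uint16(0)))
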