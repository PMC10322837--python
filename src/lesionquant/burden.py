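"""H&E tumor-burden quantification.

Four stages, mirroring a CellProfiler-style lesion pipeline:

1. import the RGB tile and convert it to optical density;
2. unmix the OD image into per-stain density maps — hematoxylin tracks the
   dense basophilic lesions, eosin the airy eosinophilic parenchyma;
3. optionally smooth, then threshold each density map independently with
   global two-class Otsu and convert the masks to labeled objects (the
   lesion mask is cleaned with a minimum equivalent-diameter filter);
4. measure the areas and report percent tumor area.

Pixels claimed by both masks are assigned to the class with the higher
unmixed density, so tumor and normal areas are disjoint and
``tumor_percent = 100 * tumor / (tumor + normal) <= 100``. A constant
density channel (e.g. a blank tile) yields an empty mask and a warning,
never a failure; percent tumor is undefined when no tissue is detected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .errors import DegenerateImageError, InvalidInputError, InvalidParameterError
from .segmentation import (
    ObjectRecord,
    binarize,
    filter_objects,
    label_connected,
    measure_objects,
    otsu_threshold,
)
from .unmixing import HE_BASIS, StainBasis, rgb_to_optical_density, unmix_stains

log = logging.getLogger(__name__)

__all__ = ["BurdenConfig", "BurdenResult", "quantify_tumor_burden", "batch_burden"]


@dataclass(frozen=True)
class BurdenConfig:
    """Tunable settings of the tumor-burden pipeline (all have defaults)."""

    stain_basis: StainBasis = HE_BASIS
    tumor_channel: str = "hematoxylin"
    normal_channel: str = "eosin"
    smoothing_sigma_px: float = 1.0
    min_object_diameter_px: float = 5.0
    white_reference: tuple[float, float, float] = (255.0, 255.0, 255.0)
    connectivity: int = 8
    n_bins: int = 256
    percent_of_total: bool = False  # tumor/total-image instead of tumor/tissue

    def validate(self) -> None:
        if self.tumor_channel == self.normal_channel:
            raise InvalidParameterError("tumor and normal channels must differ")
        self.stain_basis.index(self.tumor_channel)
        self.stain_basis.index(self.normal_channel)
        if self.smoothing_sigma_px < 0 or self.min_object_diameter_px < 0:
            raise InvalidParameterError("sigma and min diameter must be >= 0")


@dataclass(frozen=True)
class BurdenResult:
    """Terminal statistics of one tile."""

    tumor_area_px: int
    normal_area_px: int
    tumor_percent: float | None  # None when no tissue detected
    n_lesions: int
    per_lesion: tuple[ObjectRecord, ...] = field(repr=False, default=())
    tumor_mask: np.ndarray | None = field(repr=False, default=None, compare=False)
    normal_mask: np.ndarray | None = field(repr=False, default=None, compare=False)


def _threshold_or_empty(density: np.ndarray, n_bins: int, name: str) -> np.ndarray:
    try:
        thr = otsu_threshold(density, n_bins=n_bins)
    except DegenerateImageError:
        log.warning("channel %s is constant; emitting empty mask", name)
        return np.zeros(density.shape, dtype=bool)
    return binarize(density, thr)


def quantify_tumor_burden(
    img: np.ndarray, cfg: BurdenConfig | None = None, keep_masks: bool = False
) -> BurdenResult:
    """Run the four-stage pipeline on one RGB tile.

    Parameters
    ----------
    img
        ``(rows, cols, 3)`` brightfield H&E image.
    cfg
        Pipeline settings; defaults to :class:`BurdenConfig`.
    keep_masks
        Attach the final boolean tumor/normal masks to the result (for
        saving or inspection).
    """
    cfg = cfg or BurdenConfig()
    cfg.validate()
    od = rgb_to_optical_density(img, cfg.white_reference)
    dens = unmix_stains(od, cfg.stain_basis)
    tumor_d = dens[cfg.tumor_channel]
    normal_d = dens[cfg.normal_channel]
    if cfg.smoothing_sigma_px > 0:
        tumor_d = ndi.gaussian_filter(tumor_d, sigma=cfg.smoothing_sigma_px)
        normal_d = ndi.gaussian_filter(normal_d, sigma=cfg.smoothing_sigma_px)

    tumor_mask = _threshold_or_empty(tumor_d, cfg.n_bins, cfg.tumor_channel)
    normal_mask = _threshold_or_empty(normal_d, cfg.n_bins, cfg.normal_channel)

    # lesion mask: label, drop sub-diameter speckle, back to mask
    tumor_labels = label_connected(tumor_mask, connectivity=cfg.connectivity)
    tumor_labels = filter_objects(
        tumor_labels, min_diameter_px=cfg.min_object_diameter_px
    )
    tumor_mask = tumor_labels > 0

    # disjoint overlap: contested pixels go to the denser class
    overlap = tumor_mask & normal_mask
    to_normal = overlap & (normal_d > tumor_d)
    tumor_mask &= ~to_normal
    normal_mask &= ~(overlap & ~to_normal)
    if to_normal.any():
        tumor_labels = label_connected(tumor_mask, connectivity=cfg.connectivity)
        tumor_labels = filter_objects(
            tumor_labels, min_diameter_px=cfg.min_object_diameter_px
        )
        tumor_mask = tumor_labels > 0

    lesions = measure_objects(tumor_labels)
    tumor_area = int(tumor_mask.sum())
    normal_area = int(normal_mask.sum())
    denom = img.shape[0] * img.shape[1] if cfg.percent_of_total else tumor_area + normal_area
    percent = 100.0 * tumor_area / denom if denom > 0 else None
    return BurdenResult(
        tumor_area_px=tumor_area,
        normal_area_px=normal_area,
        tumor_percent=percent,
        n_lesions=len(lesions),
        per_lesion=tuple(lesions),
        tumor_mask=tumor_mask if keep_masks else None,
        normal_mask=normal_mask if keep_masks else None,
    )


def batch_burden(paths, cfg: BurdenConfig | None = None):
    """Quantify a list of image files; returns a pandas DataFrame.

    One row per readable image (``filename, tumor_area_px, normal_area_px,
    tumor_percent, n_lesions``); unreadable files are logged and skipped and
    counted in the frame's ``attrs["n_skipped"]``.
    """
    import pandas as pd

    from .io import read_image

    paths = list(paths)
    if not paths:
        raise InvalidInputError("empty path list")
    rows = []
    skipped = 0
    for path in paths:
        try:
            img = read_image(path)
            res = quantify_tumor_burden(img, cfg)
        except Exception as exc:  # noqa: BLE001 - batch must survive bad files
            log.warning("skipping %s: %s", path, exc)
            skipped += 1
            continue
        rows.append(
            {
                "filename": str(path),
                "tumor_area_px": res.tumor_area_px,
                "normal_area_px": res.normal_area_px,
                "tumor_percent": np.nan if res.tumor_percent is None else res.tumor_percent,
                "n_lesions": res.n_lesions,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["filename", "tumor_area_px", "normal_area_px", "tumor_percent", "n_lesions"],
    )
    frame.attrs["n_skipped"] = skipped
    return frame
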