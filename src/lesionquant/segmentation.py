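"""Thresholding, object labeling, filtering, measurement and relation.

These are the shared primitives both quantification pipelines compose:
global two-class Otsu thresholding, strict binarization, connected-component
labeling with deterministic raster-scan label order, equivalent-diameter and
border filtering, per-object measurement, and the centroid parent-child
relation used to call marker-positive nuclei.

Conventions (fixed so outputs are bit-reproducible):

* Otsu operates on an ``n_bins`` histogram over the observed [min, max] and
  returns a *bin edge*; ties are broken toward the lowest threshold.
* ``binarize`` is strictly greater-than: a pixel equal to the threshold is
  background.
* Labels are consecutive ``1..n`` in raster-scan order of each component's
  first-encountered pixel; background is 0.
* Coordinates are 0-based row-major with pixel centers at integer
  coordinates; centroids are rounded half-away-from-zero when tested for
  parent membership.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .errors import DegenerateImageError, InvalidInputError, InvalidParameterError

__all__ = [
    "ObjectRecord",
    "RelationMap",
    "otsu_threshold",
    "binarize",
    "label_connected",
    "filter_objects",
    "measure_objects",
    "relate_by_centroid",
    "declump_watershed",
    "equivalent_diameter",
]

UNRELATED = "unrelated"


def equivalent_diameter(area_px: float) -> float:
    """Diameter of the circle whose area equals ``area_px``: 2*sqrt(A/pi)."""
    return 2.0 * math.sqrt(area_px / math.pi)


@dataclass(frozen=True)
class ObjectRecord:
    """Per-object measurements of one labeled region."""

    label: int
    area_px: int
    centroid: tuple[float, float]  # (row, col), 0-based pixel centers
    equivalent_diameter_px: float
    mean_intensity: tuple[float, ...] | None = None


@dataclass(frozen=True)
class RelationMap:
    """Child label -> parent label (or ``"unrelated"``) assignment."""

    assignments: dict[int, int | str]
    child_name: str = "children"
    parent_name: str = "parents"

    def parent_of(self, child_label: int) -> int | str:
        return self.assignments[child_label]

    def related_children(self, parent_label: int) -> list[int]:
        return [c for c, p in self.assignments.items() if p == parent_label]


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Global two-class Otsu threshold of an image histogram.

    Builds an ``n_bins`` histogram over the observed [min, max], then returns
    the bin edge that maximizes the between-class variance
    ``w0 * w1 * (mu0 - mu1)^2`` of the two-class split (class means computed
    from bin centers). Among tied maximizers the lowest edge is returned.

    Raises
    ------
    DegenerateImageError
        If the image is constant (no threshold can split it).
    """
    if n_bins < 2:
        raise InvalidParameterError("n_bins must be >= 2")
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise InvalidInputError("empty image")
    vmin, vmax = float(v.min()), float(v.max())
    if vmin == vmax:
        raise DegenerateImageError("constant image has no Otsu threshold")
    hist, edges = np.histogram(v, bins=n_bins, range=(vmin, vmax))
    # Between-class variance is invariant (up to a positive factor) under the
    # affine map bin index -> bin center, so the maximizing cut can be found
    # on integer index moments: var(k) proportional to
    # (S0*N - S*N0)^2 / (N0*(N - N0)). Exact integer arithmetic makes the
    # lowest-threshold tie-break deterministic.
    h = hist.tolist()
    n_total = sum(h)
    s_total = sum(i * c for i, c in enumerate(h))
    best_num, best_den, best_k = -1, 1, 0
    n0 = s0 = 0
    for k in range(n_bins - 1):
        n0 += h[k]
        s0 += k * h[k]
        if n0 == 0 or n0 == n_total:
            continue
        num = (s0 * n_total - s_total * n0) ** 2
        den = n0 * (n_total - n0)
        if num * best_den > best_num * den:  # strict: first maximizer wins
            best_num, best_den, best_k = num, den, k
    return float(edges[best_k + 1])


def binarize(img: np.ndarray, threshold: float) -> np.ndarray:
    """Foreground iff pixel value is strictly greater than ``threshold``."""
    return np.asarray(img) > threshold


_STRUCTS = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def label_connected(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label maximal connected foreground components.

    Components are numbered ``1..n`` by raster-scan order of their
    first-encountered pixel; background stays 0.
    """
    if connectivity not in _STRUCTS:
        raise InvalidParameterError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise InvalidInputError("mask must be 2-D")
    raw, n = ndi.label(mask, structure=_STRUCTS[connectivity])
    if n == 0:
        return raw
    # enforce raster-scan first-encounter ordering regardless of scipy's
    # internal label assignment
    flat = raw.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier positions overwrite later ones
    first[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first[1:], kind="stable")  # old label-1 sorted by first pixel
    remap = np.zeros(n + 1, dtype=raw.dtype)
    remap[order + 1] = np.arange(1, n + 1)
    return remap[raw]


def _relabel_consecutive(labels: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Keep only labels in ``keep`` and renumber 1..m preserving order."""
    labels = np.asarray(labels)
    remap = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    remap[np.sort(keep)] = np.arange(1, len(keep) + 1)
    return remap[labels]


def filter_objects(
    labels: np.ndarray,
    min_diameter_px: float = 0.0,
    max_diameter_px: float | None = None,
    discard_border: bool = False,
) -> np.ndarray:
    """Remove objects by equivalent-diameter range and (optionally) border contact.

    Survivors are relabeled consecutively ``1..m`` preserving original order.
    """
    if max_diameter_px is not None and min_diameter_px > max_diameter_px:
        raise InvalidParameterError("min_diameter_px > max_diameter_px")
    labels = np.asarray(labels)
    n = int(labels.max())
    if n == 0:
        return labels.copy()
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    diam = 2.0 * np.sqrt(areas / np.pi)
    ok = diam >= min_diameter_px
    if max_diameter_px is not None:
        ok &= diam <= max_diameter_px
    if discard_border:
        border = np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
        on_border = np.zeros(n + 1, dtype=bool)
        on_border[border] = True
        ok &= ~on_border[1:]
    keep = np.flatnonzero(ok) + 1
    return _relabel_consecutive(labels, keep)


def measure_objects(
    labels: np.ndarray, intensity: np.ndarray | list[np.ndarray] | None = None
) -> list[ObjectRecord]:
    """Measure area, centroid, equivalent diameter and mean intensity per object.

    ``intensity`` may be one image or a list of same-shaped images; mean
    intensity is then reported per channel in that order.
    """
    labels = np.asarray(labels)
    channels: list[np.ndarray] = []
    if intensity is not None:
        channels = [np.asarray(c, dtype=float) for c in (
            [intensity] if isinstance(intensity, np.ndarray) else list(intensity)
        )]
        for c in channels:
            if c.shape != labels.shape:
                raise InvalidInputError(
                    f"intensity shape {c.shape} != label shape {labels.shape}"
                )
    stacked = np.stack(channels, axis=-1) if channels else None
    records = []
    for rp in regionprops(labels, intensity_image=stacked):
        mean = None
        if stacked is not None:
            mean = tuple(np.atleast_1d(rp.intensity_mean).astype(float).tolist())
        records.append(
            ObjectRecord(
                label=int(rp.label),
                area_px=int(rp.area),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                equivalent_diameter_px=equivalent_diameter(rp.area),
                mean_intensity=mean,
            )
        )
    records.sort(key=lambda r: r.label)
    return records


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def relate_by_centroid(
    children: np.ndarray,
    parents: np.ndarray,
    child_name: str = "children",
    parent_name: str = "parents",
) -> RelationMap:
    """Assign each child object to the parent whose mask contains its centroid.

    The child's centroid is rounded to the nearest pixel (half away from
    zero) and looked up in the parent label map; background yields
    ``"unrelated"``.
    """
    children = np.asarray(children)
    parents = np.asarray(parents)
    if children.shape != parents.shape:
        raise InvalidInputError(
            f"children shape {children.shape} != parents shape {parents.shape}"
        )
    assignments: dict[int, int | str] = {}
    for rec in measure_objects(children):
        r = _round_half_away(rec.centroid[0])
        c = _round_half_away(rec.centroid[1])
        r = min(max(r, 0), parents.shape[0] - 1)
        c = min(max(c, 0), parents.shape[1] - 1)
        parent = int(parents[r, c])
        assignments[rec.label] = parent if parent > 0 else UNRELATED
    return RelationMap(assignments, child_name=child_name, parent_name=parent_name)


def declump_watershed(
    mask: np.ndarray, min_distance_px: float = 3.0, connectivity: int = 8
) -> np.ndarray:
    """Optional distance-transform watershed split of touching objects.

    Seeds are the regional maxima of the Euclidean distance transform
    (suppressed below ``min_distance_px``); off by default in both pipelines.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    smoothed = ndi.gaussian_filter(dist, sigma=1.0)
    maxima = (smoothed == ndi.maximum_filter(smoothed, size=3)) & (
        dist >= min_distance_px
    )
    seeds, n_seeds = ndi.label(maxima, structure=_STRUCTS[connectivity])
    if n_seeds == 0:
        return label_connected(mask, connectivity=connectivity)
    split = watershed(-dist, markers=seeds, mask=mask)
    # renumber to raster-scan first-encounter order
    out = np.zeros_like(split, dtype=np.int32)
    next_label = 1
    seen: dict[int, int] = {}
    for val in split.ravel():
        if val and val not in seen:
            seen[val] = next_label
            next_label += 1
    remap = np.zeros(int(split.max()) + 1, dtype=np.int32)
    for old, new in seen.items():
        remap[old] = new
    out = remap[split]
    return out
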