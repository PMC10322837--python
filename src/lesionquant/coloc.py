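"""EdU/UHRF1 co-localization quantification in three-channel fluorescence.

Per field: the Hoechst (nuclei), FITC (EdU) and Cy5 (UHRF1) channels are
segmented independently — smoothing, global Otsu threshold, connected
components, typical-diameter and border filtering — and each marker object
is related to a nucleus by the centroid rule: a nucleus is marker-positive
iff at least one marker object's rounded centroid falls inside its mask.
A nucleus positive for both markers is double-positive.

Two percentage conventions are reported side by side, since either
denominator is defensible: double-positives as a share of all nuclei
(``pct_double_of_nuclei``) and as a share of UHRF1+ nuclei
(``pct_double_of_uhrf1``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import DegenerateImageError, InvalidInputError, InvalidParameterError
from .segmentation import (
    binarize,
    filter_objects,
    label_connected,
    otsu_threshold,
    relate_by_centroid,
)

log = logging.getLogger(__name__)

__all__ = [
    "ChannelConfig",
    "NucleusCall",
    "ColocResult",
    "segment_channel",
    "call_markers",
    "quantify_colocalization",
    "DEFAULT_CHANNEL_CONFIGS",
]


@dataclass(frozen=True)
class ChannelConfig:
    """Segmentation settings for one fluorescence channel."""

    role: str  # "nuclei" | "edu" | "uhrf1"
    typical_diameter_px: tuple[float, float] = (6.0, 40.0)
    smoothing_sigma_px: float = 1.0
    discard_border: bool = True
    connectivity: int = 8
    n_bins: int = 256

    def validate(self) -> None:
        lo, hi = self.typical_diameter_px
        if not 0 <= lo < hi:
            raise InvalidParameterError("typical_diameter_px must satisfy min < max")
        if self.smoothing_sigma_px < 0:
            raise InvalidParameterError("smoothing sigma must be >= 0")
        if self.role not in {"nuclei", "edu", "uhrf1"}:
            raise InvalidParameterError(f"unknown channel role {self.role!r}")


DEFAULT_CHANNEL_CONFIGS: dict[str, ChannelConfig] = {
    "nuclei": ChannelConfig(role="nuclei"),
    "edu": ChannelConfig(role="edu", discard_border=False),
    "uhrf1": ChannelConfig(role="uhrf1", discard_border=False),
}


@dataclass(frozen=True)
class NucleusCall:
    nucleus_label: int
    edu_positive: bool
    uhrf1_positive: bool

    @property
    def double_positive(self) -> bool:
        return self.edu_positive and self.uhrf1_positive


@dataclass(frozen=True)
class ColocResult:
    """Per-field counts and the two percentage conventions."""

    n_nuclei: int
    n_edu_pos: int
    n_uhrf1_pos: int
    n_double: int

    @property
    def pct_double_of_nuclei(self) -> float | None:
        if self.n_nuclei == 0:
            return None
        return 100.0 * self.n_double / self.n_nuclei

    @property
    def pct_double_of_uhrf1(self) -> float | None:
        if self.n_uhrf1_pos == 0:
            return None
        return 100.0 * self.n_double / self.n_uhrf1_pos


def segment_channel(img: np.ndarray, cfg: ChannelConfig) -> np.ndarray:
    """Smooth, Otsu-threshold, label and size/border-filter one channel.

    A constant (blank) channel yields an empty label map with a warning,
    not an error.
    """
    cfg.validate()
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise InvalidInputError(f"expected a single-channel image; got shape {img.shape}")
    if cfg.smoothing_sigma_px > 0:
        img = ndi.gaussian_filter(img, sigma=cfg.smoothing_sigma_px)
    try:
        thr = otsu_threshold(img, n_bins=cfg.n_bins)
    except DegenerateImageError:
        log.warning("channel %r is constant; no objects", cfg.role)
        return np.zeros(img.shape, dtype=np.int32)
    labels = label_connected(binarize(img, thr), connectivity=cfg.connectivity)
    lo, hi = cfg.typical_diameter_px
    return filter_objects(
        labels,
        min_diameter_px=lo,
        max_diameter_px=hi,
        discard_border=cfg.discard_border,
    )


def _positive_nuclei(
    marker: np.ndarray, nuclei: np.ndarray, name: str, reverse: bool
) -> set[int]:
    if reverse:
        # nucleus centroid inside a marker object
        rel = relate_by_centroid(nuclei, marker, child_name="nuclei", parent_name=name)
        return {c for c, p in rel.assignments.items() if isinstance(p, int)}
    rel = relate_by_centroid(marker, nuclei, child_name=name, parent_name="nuclei")
    return {p for p in rel.assignments.values() if isinstance(p, int)}


def call_markers(
    nuclei: np.ndarray,
    edu: np.ndarray,
    uhrf1: np.ndarray,
    reverse_relation: bool = False,
) -> list[NucleusCall]:
    """Flag each nucleus EdU+/UHRF1+ by centroid relation of marker objects.

    A nucleus is positive for a marker iff >= 1 object of that marker's
    label map has its rounded centroid inside the nucleus mask; multiple
    related objects still count once. With ``reverse_relation`` the test is
    inverted (nucleus centroid inside a marker object).
    """
    nuclei = np.asarray(nuclei)
    for name, m in (("edu", edu), ("uhrf1", uhrf1)):
        if np.asarray(m).shape != nuclei.shape:
            raise InvalidInputError(f"{name} map shape mismatch with nuclei")
    edu_parents = _positive_nuclei(edu, nuclei, "edu", reverse_relation)
    uhrf1_parents = _positive_nuclei(uhrf1, nuclei, "uhrf1", reverse_relation)
    n = int(nuclei.max())
    return [
        NucleusCall(
            nucleus_label=lab,
            edu_positive=lab in edu_parents,
            uhrf1_positive=lab in uhrf1_parents,
        )
        for lab in range(1, n + 1)
    ]


def quantify_colocalization(
    hoechst: np.ndarray,
    edu: np.ndarray,
    uhrf1: np.ndarray,
    cfgs: dict[str, ChannelConfig] | None = None,
) -> ColocResult:
    """Segment all three channels, call markers and aggregate counts."""
    cfgs = cfgs or DEFAULT_CHANNEL_CONFIGS
    for role in ("nuclei", "edu", "uhrf1"):
        if role not in cfgs:
            raise InvalidInputError(f"missing channel config for {role!r}")
    shapes = {np.asarray(c).shape for c in (hoechst, edu, uhrf1)}
    if len(shapes) != 1:
        raise InvalidInputError(f"channel shapes differ: {shapes}")
    nuc_labels = segment_channel(hoechst, cfgs["nuclei"])
    edu_labels = segment_channel(edu, cfgs["edu"])
    uhrf1_labels = segment_channel(uhrf1, cfgs["uhrf1"])
    calls = call_markers(nuc_labels, edu_labels, uhrf1_labels)
    return ColocResult(
        n_nuclei=len(calls),
        n_edu_pos=sum(c.edu_positive for c in calls),
        n_uhrf1_pos=sum(c.uhrf1_positive for c in calls),
        n_double=sum(c.double_positive for c in calls),
    )
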