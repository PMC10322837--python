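"""Ground-truth simulators for the two quantification pipelines.

The study's raw histology and fluorescence images are not deposited, so
parameter-recovery testing runs on synthetic fields with exact per-pixel /
per-nucleus ground truth:

* :func:`make_he_tile` renders an H&E-like brightfield tile through the
  Beer-Lambert model: hematoxylin-dominant lesion blobs (unions of random
  disks) embedded in an eosin-dominant "airy" parenchyma (a thresholded
  smooth random field with white airspace holes) on a white background. The
  per-pixel tissue-class map and the realized lesion fraction are returned
  alongside the image.
* :func:`make_fluor_field` renders a three-channel fluorescence field of
  non-overlapping nuclei. Each nucleus draws its (EdU+, UHRF1+) label pair
  from an explicit 2x2 joint table so the double-positive probability is
  controlled exactly, then Hoechst renders all nuclei, FITC the EdU+ ones
  and Cy5 the UHRF1+ ones, with Gaussian blur, background and noise.

Both generators are bit-reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import GenerationError, InvalidParameterError
from .unmixing import HE_BASIS, StainBasis, render_absorbance

__all__ = [
    "SynthHEParams",
    "SynthFluorParams",
    "GroundTruthBurden",
    "NucleusTruth",
    "GroundTruthColoc",
    "make_he_tile",
    "make_fluor_field",
]

BACKGROUND, NORMAL, LESION = 0, 1, 2


@dataclass(frozen=True)
class SynthHEParams:
    """Study conditions for one synthetic H&E tile.

    ``target_tumor_fraction`` is the desired lesion share of tissue area,
    lesion px / (lesion px + normal px); disks are added until the realized
    fraction reaches it. Densities are mean optical densities (dimensionless).
    """

    image_size: tuple[int, int] = (512, 512)
    target_tumor_fraction: float = 0.30
    lesion_radius_px: tuple[float, float] = (12.0, 40.0)
    parenchyma_density: float = 0.45
    lesion_density: float = 0.90
    lesion_eosin_density: float = 0.15
    parenchyma_hematoxylin_density: float = 0.08
    airspace_fraction: float = 0.40
    density_texture_sd: float = 0.05
    noise_sd: float = 2.0  # additive Gaussian noise in 8-bit intensity units
    stain_basis: StainBasis = HE_BASIS
    white_reference: tuple[float, float, float] = (255.0, 255.0, 255.0)
    seed: int = 0
    max_disks: int = 5000

    def validate(self) -> None:
        if not 0.0 <= self.target_tumor_fraction <= 1.0:
            raise InvalidParameterError("target_tumor_fraction must be in [0, 1]")
        if not 0.0 <= self.airspace_fraction < 1.0:
            raise InvalidParameterError("airspace_fraction must be in [0, 1)")
        lo, hi = self.lesion_radius_px
        if not 0 < lo < hi:
            raise InvalidParameterError("lesion radii must satisfy 0 < min < max")
        if min(self.parenchyma_density, self.lesion_density) < 0:
            raise InvalidParameterError("densities must be >= 0")
        if min(self.image_size) <= 0:
            raise InvalidParameterError("image_size must be positive")


@dataclass(frozen=True)
class GroundTruthBurden:
    """Exact per-pixel tissue classes (0 background, 1 normal, 2 lesion)."""

    class_map: np.ndarray
    true_tumor_fraction: float


@dataclass(frozen=True)
class NucleusTruth:
    center: tuple[float, float]
    radius: float
    edu_positive: bool
    uhrf1_positive: bool


@dataclass(frozen=True)
class GroundTruthColoc:
    """Exact per-nucleus marker labels and the realized fractions."""

    nuclei: tuple[NucleusTruth, ...] = field(repr=False)

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)

    @property
    def n_edu(self) -> int:
        return sum(n.edu_positive for n in self.nuclei)

    @property
    def n_uhrf1(self) -> int:
        return sum(n.uhrf1_positive for n in self.nuclei)

    @property
    def n_double(self) -> int:
        return sum(n.edu_positive and n.uhrf1_positive for n in self.nuclei)

    @property
    def frac_double(self) -> float:
        return self.n_double / self.n_nuclei if self.n_nuclei else float("nan")


def _smooth_field(rng: np.random.Generator, shape, sigma: float = 8.0) -> np.ndarray:
    noise = rng.standard_normal(shape)
    return ndi.gaussian_filter(noise, sigma=sigma)


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def make_he_tile(params: SynthHEParams) -> tuple[np.ndarray, GroundTruthBurden]:
    """Render one synthetic H&E tile and its exact ground truth.

    Returns
    -------
    (image, truth)
        ``image`` is an 8-bit ``(rows, cols, 3)`` RGB array; ``truth`` holds
        the per-pixel class map and the realized lesion fraction of tissue.
    """
    params.validate()
    shape = tuple(params.image_size)
    seq = np.random.SeedSequence(params.seed)
    rng_parenchyma, rng_lesion, rng_noise = (
        np.random.default_rng(s) for s in seq.spawn(3)
    )

    # parenchyma: smooth random field thresholded at the airspace quantile,
    # so airspace_fraction of the tile stays white
    fld = _smooth_field(rng_parenchyma, shape)
    cut = np.quantile(fld, params.airspace_fraction)
    parenchyma = fld > cut

    # lesions: add random disks until the lesion share of tissue reaches the
    # target; the disk stream depends only on rng_lesion, so raising the
    # target with the same seed extends (never reshuffles) the lesion set
    lesion = np.zeros(shape, dtype=bool)
    target = params.target_tumor_fraction
    if target > 0:
        lo, hi = params.lesion_radius_px
        for _ in range(params.max_disks):
            lesion_px = int(lesion.sum())
            normal_px = int((parenchyma & ~lesion).sum())
            tissue = lesion_px + normal_px
            if tissue > 0 and lesion_px / tissue >= target:
                break
            center = (
                rng_lesion.uniform(0, shape[0]),
                rng_lesion.uniform(0, shape[1]),
            )
            radius = rng_lesion.uniform(lo, hi)
            lesion |= _disk_mask(shape, center, radius)
        else:
            raise GenerationError(
                f"could not reach lesion fraction {target} in "
                f"{params.max_disks} disks"
            )

    class_map = np.zeros(shape, dtype=np.uint8)
    class_map[parenchyma] = NORMAL
    class_map[lesion] = LESION
    lesion_px = int((class_map == LESION).sum())
    normal_px = int((class_map == NORMAL).sum())
    tissue = lesion_px + normal_px
    true_fraction = lesion_px / tissue if tissue else 0.0

    # per-stain density maps with mild multiplicative texture
    names = params.stain_basis.names
    dens = np.zeros(shape + (len(names),), dtype=float)
    tex = 1.0 + params.density_texture_sd * rng_parenchyma.standard_normal(shape)
    tex = np.clip(tex, 0.0, None)
    hema = params.stain_basis.index("hematoxylin")
    eos = params.stain_basis.index("eosin")
    dens[class_map == LESION, hema] = params.lesion_density
    dens[class_map == LESION, eos] = params.lesion_eosin_density
    dens[class_map == NORMAL, eos] = params.parenchyma_density
    dens[class_map == NORMAL, hema] = params.parenchyma_hematoxylin_density
    dens *= tex[..., None]

    img = render_absorbance(dens, params.stain_basis, params.white_reference)
    if params.noise_sd > 0:
        img = img + params.noise_sd * rng_noise.standard_normal(img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img, GroundTruthBurden(class_map=class_map, true_tumor_fraction=true_fraction)


@dataclass(frozen=True)
class SynthFluorParams:
    """Study conditions for one synthetic three-channel fluorescence field.

    ``p_edu`` and ``p_uhrf1`` are marginal positivity probabilities and
    ``p_both`` the joint; they must satisfy the Frechet bounds
    ``max(0, p_edu + p_uhrf1 - 1) <= p_both <= min(p_edu, p_uhrf1)``.
    Nuclei are non-overlapping by construction and placed fully inside the
    field (a small margin keeps blurred disks off the border).
    """

    image_size: tuple[int, int] = (1024, 1024)
    n_nuclei: int = 300
    nucleus_radius_px: tuple[float, float] = (5.0, 8.0)
    p_edu: float = 0.40
    p_uhrf1: float = 0.30
    p_both: float = 0.20
    blur_sigma_px: float = 1.0
    noise_sd: float = 0.01  # on the normalized [0, 1] intensity scale
    background_level: float = 0.05
    nucleus_intensity: float = 0.80
    border_margin_px: float = 4.0
    seed: int = 0
    max_retries: int = 1000

    def validate(self) -> None:
        for name, p in (("p_edu", self.p_edu), ("p_uhrf1", self.p_uhrf1)):
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1]")
        lo = max(0.0, self.p_edu + self.p_uhrf1 - 1.0)
        hi = min(self.p_edu, self.p_uhrf1)
        if not lo - 1e-12 <= self.p_both <= hi + 1e-12:
            raise InvalidParameterError(
                f"p_both={self.p_both} violates Frechet bounds [{lo}, {hi}]"
            )
        rlo, rhi = self.nucleus_radius_px
        if not 0 < rlo < rhi:
            raise InvalidParameterError("nucleus radii must satisfy 0 < min < max")
        if self.n_nuclei < 0:
            raise InvalidParameterError("n_nuclei must be >= 0")


def _draw_labels(rng: np.random.Generator, p: SynthFluorParams, n: int):
    """Draw (edu, uhrf1) pairs from the explicit 2x2 joint table."""
    probs = np.array(
        [
            p.p_both,  # both
            p.p_edu - p.p_both,  # edu only
            p.p_uhrf1 - p.p_both,  # uhrf1 only
            1.0 - p.p_edu - p.p_uhrf1 + p.p_both,  # neither
        ]
    )
    probs = np.clip(probs, 0.0, None)
    probs = probs / probs.sum()
    cats = rng.choice(4, size=n, p=probs)
    edu = (cats == 0) | (cats == 1)
    uhrf1 = (cats == 0) | (cats == 2)
    return edu, uhrf1


def make_fluor_field(
    params: SynthFluorParams,
) -> tuple[dict[str, np.ndarray], GroundTruthColoc]:
    """Render one synthetic fluorescence field and its exact ground truth.

    Returns
    -------
    (channels, truth)
        ``channels`` maps ``"hoechst"``, ``"edu"``, ``"uhrf1"`` to 8-bit
        single-channel images; ``truth`` lists every nucleus with its center,
        radius and marker labels.
    """
    params.validate()
    shape = tuple(params.image_size)
    seq = np.random.SeedSequence(params.seed)
    rng_place, rng_label, rng_noise = (
        np.random.default_rng(s) for s in seq.spawn(3)
    )

    rlo, rhi = params.nucleus_radius_px
    margin = rhi + params.border_margin_px
    if shape[0] <= 2 * margin or shape[1] <= 2 * margin:
        raise InvalidParameterError("image too small for nucleus radius + margin")

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    min_gap = 2.0  # clearance between disk edges, keeps objects separable
    for _ in range(params.n_nuclei):
        for _attempt in range(params.max_retries):
            r = rng_place.uniform(rlo, rhi)
            cy = rng_place.uniform(margin, shape[0] - margin)
            cx = rng_place.uniform(margin, shape[1] - margin)
            ok = all(
                (cy - oy) ** 2 + (cx - ox) ** 2 >= (r + orad + min_gap) ** 2
                for (oy, ox), orad in zip(centers, radii)
            )
            if ok:
                centers.append((cy, cx))
                radii.append(r)
                break
        else:
            raise GenerationError(
                f"placed only {len(centers)}/{params.n_nuclei} nuclei in "
                f"{params.max_retries} retries each; density too high"
            )

    edu_flags, uhrf1_flags = _draw_labels(rng_label, params, len(centers))

    hoechst = np.zeros(shape, dtype=float)
    fitc = np.zeros(shape, dtype=float)
    cy5 = np.zeros(shape, dtype=float)
    for (cy, cx), r, e, u in zip(centers, radii, edu_flags, uhrf1_flags):
        # paint only the disk's bounding box
        r0, r1 = int(np.floor(cy - r)) - 1, int(np.ceil(cy + r)) + 2
        c0, c1 = int(np.floor(cx - r)) - 1, int(np.ceil(cx + r)) + 2
        r0, c0 = max(r0, 0), max(c0, 0)
        rr, cc = np.ogrid[r0:r1, c0:c1]
        disk = (rr - cy) ** 2 + (cc - cx) ** 2 <= r**2
        win = (slice(r0, r1), slice(c0, c1))
        hoechst[win][disk] = params.nucleus_intensity
        if e:
            fitc[win][disk] = params.nucleus_intensity
        if u:
            cy5[win][disk] = params.nucleus_intensity

    channels = {}
    for name, plane in (("hoechst", hoechst), ("edu", fitc), ("uhrf1", cy5)):
        if params.blur_sigma_px > 0:
            plane = ndi.gaussian_filter(plane, sigma=params.blur_sigma_px)
        plane = plane + params.background_level
        if params.noise_sd > 0:
            plane = plane + params.noise_sd * rng_noise.standard_normal(shape)
        channels[name] = np.clip(np.round(plane * 255.0), 0, 255).astype(np.uint8)

    truth = GroundTruthColoc(
        nuclei=tuple(
            NucleusTruth(center=c, radius=r, edu_positive=bool(e), uhrf1_positive=bool(u))
            for c, r, e, u in zip(centers, radii, edu_flags, uhrf1_flags)
        )
    )
    return channels, truth
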