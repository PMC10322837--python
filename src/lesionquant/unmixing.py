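"""Optical-density transform and linear stain unmixing.

Brightfield stains absorb light, so per-pixel absorbances add linearly in
optical-density (OD) space (Beer-Lambert law):

    OD_c = -log10(I_c / W_c),   I = W * 10^(-sum_s d_s * v_s,c)

where ``I_c`` is the transmitted intensity in channel ``c``, ``W_c`` the
white (incident-light) reference, ``d_s`` the amount of stain ``s`` at the
pixel and ``v_s`` its unit absorbance vector. Unmixing solves the per-pixel
least-squares system for the stain amounts ``d_s`` and clamps negative
solutions to zero, yielding one non-negative density map per stain — for an
H&E section, a hematoxylin map (dense basophilic lesions) and an eosin map
(eosinophilic parenchyma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError, SingularBasisError

__all__ = [
    "StainBasis",
    "HE_BASIS",
    "rgb_to_optical_density",
    "unmix_stains",
    "render_absorbance",
]

#: Relative floor for the log transform: intensities below
#: ``EPS_FRACTION * white_reference`` are clipped before taking log10, so a
#: zero pixel maps to a large finite OD instead of infinity.
EPS_FRACTION = 1.0 / 255.0


@dataclass(frozen=True)
class StainBasis:
    """Ordered set of unit absorbance vectors, one per stain.

    Parameters
    ----------
    stains
        Mapping-style list of ``(name, rgb_absorbance)`` pairs. Vectors are
        normalized to unit Euclidean length on construction; components must
        be non-negative and not all zero.
    """

    stains: tuple[tuple[str, tuple[float, float, float]], ...] = field()

    def __init__(self, stains) -> None:
        normed = []
        for name, vec in stains:
            v = np.asarray(vec, dtype=float)
            if v.shape != (3,):
                raise InvalidParameterError(
                    f"stain {name!r}: absorbance vector must have 3 components"
                )
            if np.any(v < 0):
                raise InvalidParameterError(
                    f"stain {name!r}: absorbance components must be >= 0"
                )
            norm = float(np.linalg.norm(v))
            if norm == 0.0:
                raise InvalidParameterError(
                    f"stain {name!r}: absorbance vector must be non-zero"
                )
            normed.append((str(name), tuple((v / norm).tolist())))
        if not 1 <= len(normed) <= 3:
            raise InvalidParameterError("basis must contain 1-3 stains")
        if len({n for n, _ in normed}) != len(normed):
            raise InvalidParameterError("stain names must be unique")
        object.__setattr__(self, "stains", tuple(normed))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.stains)

    def matrix(self) -> np.ndarray:
        """Return the 3 x n_stains matrix whose columns are the unit vectors."""
        return np.stack([np.asarray(v) for _, v in self.stains], axis=1)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise InvalidParameterError(
                f"stain {name!r} not in basis {self.names}"
            ) from None


#: Literature H&E absorbance vectors (Ruifrok & Johnston color-deconvolution
#: constants), unit-normalized. Configuration defaults, overridable.
HE_BASIS = StainBasis(
    [
        ("hematoxylin", (0.650, 0.704, 0.286)),
        ("eosin", (0.072, 0.990, 0.105)),
    ]
)


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise InvalidInputError(
            f"expected an RGB image (rows, cols, 3); got shape {img.shape}"
        )
    if img.shape[0] == 0 or img.shape[1] == 0:
        raise InvalidInputError("image is empty")
    return img


def rgb_to_optical_density(
    img: np.ndarray, white_reference=(255.0, 255.0, 255.0)
) -> np.ndarray:
    """Convert a brightfield RGB image to per-channel optical density.

    ``OD_c = -log10(max(I_c, eps_c) / W_c)`` clamped to >= 0, with
    ``eps_c = W_c / 255`` preventing log of zero. A pixel equal to the white
    reference maps to OD (0, 0, 0).

    Parameters
    ----------
    img
        ``(rows, cols, 3)`` intensities, any non-negative scale.
    white_reference
        Incident-light intensity per channel; must be strictly positive.

    Returns
    -------
    ``(rows, cols, 3)`` float OD image aligned to the input grid.
    """
    img = _check_rgb(img)
    white = np.asarray(white_reference, dtype=float)
    if white.shape != (3,) or np.any(white <= 0):
        raise InvalidParameterError("white_reference must be 3 positive scalars")
    if np.any(img < 0):
        raise InvalidInputError("pixel intensities must be >= 0")
    floored = np.maximum(img, white * EPS_FRACTION)
    od = -np.log10(floored / white)
    return np.maximum(od, 0.0)


def render_absorbance(
    densities: np.ndarray, basis: StainBasis, white_reference=(255.0, 255.0, 255.0)
) -> np.ndarray:
    """Forward Beer-Lambert render: stain densities -> transmitted RGB floats.

    ``I = W * 10^(-D @ M.T)`` where ``D`` is ``(rows, cols, n_stains)`` and
    ``M`` the basis matrix. Inverse of OD transform + unmixing on noise-free
    input; shared by the H&E simulator and the round-trip tests.
    """
    densities = np.asarray(densities, dtype=float)
    white = np.asarray(white_reference, dtype=float)
    od = densities @ basis.matrix().T
    return white * np.power(10.0, -od)


def unmix_stains(od: np.ndarray, basis: StainBasis) -> dict[str, np.ndarray]:
    """Per-pixel least-squares separation of an OD image into stain densities.

    Solves ``M d = od`` for each pixel (``M`` = 3 x n_stains basis matrix) by
    least squares and clamps negative components to zero.

    Returns
    -------
    dict mapping stain name -> ``(rows, cols)`` non-negative density map.

    Raises
    ------
    SingularBasisError
        If the basis vectors are linearly dependent.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[-1] != 3:
        raise InvalidInputError(
            f"expected an OD image (rows, cols, 3); got shape {od.shape}"
        )
    m = basis.matrix()
    if np.linalg.matrix_rank(m, tol=1e-10) < m.shape[1]:
        raise SingularBasisError(
            f"stain vectors {basis.names} are linearly dependent"
        )
    # pinv(M) @ od is the least-squares solution for every pixel at once
    pinv = np.linalg.pinv(m)
    dens = od @ pinv.T
    dens = np.maximum(dens, 0.0)
    return {name: dens[..., i] for i, name in enumerate(basis.names)}
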