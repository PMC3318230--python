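"""Image and patch data model shared by all filters.

Images are plain 2-D ``float64`` :class:`numpy.ndarray` objects holding
nonnegative magnitude intensities.  Coordinates are 0-based ``(row, col)``
with the origin at the top-left corner; every module in the package uses this
convention.

The filters measure patch similarity inside a square search window, so every
pixel needs a full ``S x S`` window of full ``r x r`` patches around it.
Mirror-reflect padding by ``(S - 1)/2 + (r - 1)/2`` provides that; the
interior of the padded image is the original image, so weight normalisation
is uniform everywhere including at the borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "PatchSpec",
    "SearchSpec",
    "FilterParams",
    "METHODS",
    "as_image",
    "pad_reflect",
    "extract_patch",
    "window_indices",
]

#: Supported filter estimators.
METHODS = ("nlm", "nlm-dct", "unlm", "unlm-dct")


def as_image(values) -> np.ndarray:
    """Coerce ``values`` to a finite 2-D float64 image array.

    Integer inputs are promoted to double precision; NaN/inf raise.
    """
    img = np.asarray(values, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if img.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


@dataclass(frozen=True)
class PatchSpec:
    """Square ``r x r`` similarity neighbourhood.

    ``r`` must be odd so the patch has a centre pixel.  ``M = r * r`` is the
    patch pixel count and the dimension of the full DCT coefficient space.
    """

    r: int = 5

    def __post_init__(self) -> None:
        if self.r < 1 or self.r % 2 == 0:
            raise ValueError(f"patch side r must be odd and positive, got {self.r}")

    @property
    def M(self) -> int:
        return self.r * self.r

    @property
    def half(self) -> int:
        return self.r // 2


@dataclass(frozen=True)
class SearchSpec:
    """Square ``S x S`` search window centred on the pixel being estimated."""

    S: int = 11

    def __post_init__(self) -> None:
        if self.S < 1 or self.S % 2 == 0:
            raise ValueError(f"search side S must be odd and positive, got {self.S}")

    @property
    def half(self) -> int:
        return self.S // 2


@dataclass(frozen=True)
class FilterParams:
    """Complete parameterisation of one denoising run.

    Parameters
    ----------
    method:
        One of ``"nlm"``, ``"nlm-dct"``, ``"unlm"``, ``"unlm-dct"``.
    h:
        Smoothing bandwidth of the exponential weight kernel, in intensity
        units.  The squared patch distance is *not* divided by the patch
        pixel count, so useful ``h`` values are large (order ``sigma *
        sqrt(M)``).
    d:
        DCT subspace dimension for the DCT-based methods: the number of
        leading zigzag-ordered coefficients entering the patch distance.
        ``d = M`` makes NLM-DCT identical to plain NLM.  Ignored by the
        full-space methods.
    sigma:
        Rician noise standard deviation; required by the unbiased methods.
    center_weight:
        ``"self"`` keeps the self-weight exactly as the weight formula gives
        it (unit pre-normalisation weight, the default); ``"max"`` replaces
        the centre weight by the maximal off-centre weight, a common
        heuristic offered as an option only.
    """

    method: str = "nlm"
    h: float = 1.0
    d: int | None = None
    sigma: float | None = None
    patch: PatchSpec = field(default_factory=PatchSpec)
    search: SearchSpec = field(default_factory=SearchSpec)
    center_weight: str = "self"

    def __post_init__(self) -> None:
        method = self.method.lower().replace("_", "-")
        object.__setattr__(self, "method", method)
        if method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if not (self.h > 0):
            raise ValueError(f"smoothing parameter h must be positive, got {self.h}")
        if self.search.S < self.patch.r:
            raise ValueError("search window must be at least as large as the patch")
        if self.uses_dct:
            d = self.patch.M if self.d is None else int(self.d)
            if not 1 <= d <= self.patch.M:
                raise ValueError(f"d must be in [1, {self.patch.M}], got {self.d}")
            object.__setattr__(self, "d", d)
        if self.unbiased:
            if self.sigma is None:
                raise ValueError(f"method {method!r} requires sigma")
            if self.sigma < 0:
                raise ValueError(f"sigma must be nonnegative, got {self.sigma}")
        if self.center_weight not in ("self", "max"):
            raise ValueError("center_weight must be 'self' or 'max'")

    @property
    def uses_dct(self) -> bool:
        return self.method in ("nlm-dct", "unlm-dct")

    @property
    def unbiased(self) -> bool:
        return self.method in ("unlm", "unlm-dct")

    @property
    def pad(self) -> int:
        """Margin needed so every pixel has a full window of full patches."""
        return self.search.half + self.patch.half


def pad_reflect(image: np.ndarray, margin: int) -> np.ndarray:
    """Mirror-reflect pad ``image`` by ``margin`` pixels on every side.

    The reflection does not repeat the edge pixel (``[1, 2, 3]`` padded by
    one becomes ``[2, 1, 2, 3, 2]``).  A 1-pixel-wide axis is extended with
    its single value, the only reflection possible.
    """
    image = as_image(image)
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    if margin == 0:
        return image.copy()
    if margin > min(image.shape):
        raise ValueError(
            f"margin {margin} too large for image of shape {image.shape}"
        )
    if 1 in image.shape:
        # np.pad(mode="reflect") requires >= 2 samples along the axis; a
        # single sample reflects onto itself.
        mode = "reflect" if min(image.shape) > 1 else "edge"
        out = image
        for axis, n in enumerate(image.shape):
            pad = [(0, 0), (0, 0)]
            pad[axis] = (margin, margin)
            out = np.pad(out, pad, mode="edge" if n == 1 else "reflect")
        return out
    return np.pad(image, margin, mode="reflect")


def extract_patch(image: np.ndarray, center: tuple[int, int], patch: PatchSpec) -> np.ndarray:
    """Return the ``r x r`` submatrix of ``image`` centred at ``center``.

    The caller is expected to have padded the image; a window that exceeds
    the image bounds raises ``IndexError``.
    """
    image = np.asarray(image, dtype=np.float64)
    y, x = center
    h = patch.half
    if y - h < 0 or x - h < 0 or y + h >= image.shape[0] or x + h >= image.shape[1]:
        raise IndexError(
            f"patch of side {patch.r} at {center} exceeds image of shape {image.shape}; "
            "pad the image first"
        )
    return image[y - h : y + h + 1, x - h : x + h + 1]


def window_indices(
    center: tuple[int, int], search: SearchSpec, image: np.ndarray
) -> list[tuple[int, int]]:
    """Row-major coordinates of the ``S x S`` search window around ``center``.

    Exactly ``S**2`` coordinates are returned, including the centre itself.
    The image must already be padded so the window is in bounds.
    """
    y, x = center
    h = search.half
    if y - h < 0 or x - h < 0 or y + h >= image.shape[0] or x + h >= image.shape[1]:
        raise IndexError(
            f"window of side {search.S} at {center} exceeds image of shape {image.shape}"
        )
    return [(y + dy, x + dx) for dy in range(-h, h + 1) for dx in range(-h, h + 1)]
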