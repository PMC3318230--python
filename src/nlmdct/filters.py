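"""The four nonlocal-means estimators: NLM, NLM-DCT, UNLM, UNLM-DCT.

Each pixel is estimated as a convex combination of the intensities in its
search window,

    u_hat(i) = sum_{j in S_i} w(i, j) v(j),
    w(i, j)  = exp(-D2(i, j) / h^2) / Z(i),

where ``D2`` is the squared Euclidean distance between the ``r x r`` patches
around ``i`` and ``j`` (plain NLM) or between the leading ``d``
zigzag-ordered DCT coefficients of those patches (NLM-DCT), and ``Z(i)``
normalises the weights to sum to one over the window, the centre ``j = i``
included.  The distance is not divided by the patch size, so ``h`` is large
in absolute terms (order ``sigma * sqrt(M)``).

The unbiased variants (UNLM, UNLM-DCT) correct the Rician bias of magnitude
MR intensities after filtering: the squared magnitude carries a
signal-independent ``2 sigma^2`` offset, so the filtered value is squared,
the offset subtracted with clamping at zero, and the square root taken to
return to intensity units.

Implementation note: :func:`filter_image` vectorises over window *offsets* —
for each of the ``S^2`` displacements it forms the shifted squared
difference image and box-sums it over the patch, which is algebraically the
per-pixel patch distance.  :func:`weights_full` / :func:`weights_dct`
compute one pixel's weight field directly and serve as the readable
single-centre form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .dct import dct_basis, patch_to_coeffs
from .image import FilterParams, as_image, extract_patch, pad_reflect, window_indices

__all__ = [
    "WeightField",
    "DenoiseResult",
    "unbias",
    "weights_full",
    "weights_dct",
    "filter_image",
    "weight_map",
]


@dataclass(frozen=True)
class WeightField:
    """Normalised similarity weights of one search window.

    ``coords`` are padded-image coordinates in row-major window order;
    ``weights`` are the matching normalised weights (summing to one);
    ``normalizer`` is Z(i), the sum of the unnormalised weights.
    """

    center: tuple[int, int]
    coords: list[tuple[int, int]]
    weights: np.ndarray
    normalizer: float

    def as_window(self, S: int) -> np.ndarray:
        return self.weights.reshape(S, S)


@dataclass(frozen=True)
class DenoiseResult:
    """Denoised image, the residual ``noisy - denoised``, and the run parameters."""

    denoised: np.ndarray
    residual: np.ndarray
    params: FilterParams
    metrics: object | None = None


def unbias(filtered_value, sigma: float):
    """Remove the Rician bias from a filtered magnitude value.

    Returns ``sqrt(max(u_hat^2 - 2 sigma^2, 0))``: the ``2 sigma^2`` offset
    of the squared magnitude is subtracted with clamping at zero and the
    square root restores intensity units.  Monotone nondecreasing in the
    input; the identity when ``sigma = 0``.  Accepts scalars or arrays.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be nonnegative, got {sigma}")
    v = np.asarray(filtered_value, dtype=np.float64)
    out = np.sqrt(np.maximum(v * v - 2.0 * sigma * sigma, 0.0))
    return float(out) if np.isscalar(filtered_value) else out


def _apply_center_rule(w_un: np.ndarray, center_pos: int, rule: str) -> None:
    """Optionally replace the self-weight by the maximal off-centre weight."""
    if rule == "max" and w_un.size > 1:
        others = np.delete(w_un, center_pos)
        w_un[center_pos] = others.max()


def weights_full(image: np.ndarray, center: tuple[int, int], params: FilterParams) -> WeightField:
    """Full-space NLM weight field for one pixel of a padded image.

    ``center`` is a coordinate of the padded image; the full search window
    and all its patches must be in bounds.
    """
    image = as_image(image)
    coords = window_indices(center, params.search, image)
    pi = extract_patch(image, center, params.patch)
    d2 = np.empty(len(coords))
    for k, j in enumerate(coords):
        diff = pi - extract_patch(image, j, params.patch)
        d2[k] = np.sum(diff * diff)
    return _normalise(center, coords, d2, params)


def weights_dct(image: np.ndarray, center: tuple[int, int], params: FilterParams) -> WeightField:
    """DCT-subspace weight field: distances over the first ``d`` zigzag coefficients."""
    image = as_image(image)
    d = params.d if params.d is not None else params.patch.M
    if not 1 <= d <= params.patch.M:
        raise ValueError(f"d must be in [1, {params.patch.M}], got {d}")
    coords = window_indices(center, params.search, image)
    ci = patch_to_coeffs(extract_patch(image, center, params.patch))[:d]
    d2 = np.empty(len(coords))
    for k, j in enumerate(coords):
        cj = patch_to_coeffs(extract_patch(image, j, params.patch))[:d]
        diff = ci - cj
        d2[k] = diff @ diff
    return _normalise(center, coords, d2, params)


def _normalise(center, coords, d2, params: FilterParams) -> WeightField:
    w_un = np.exp(-d2 / (params.h * params.h))
    _apply_center_rule(w_un, coords.index(center), params.center_weight)
    Z = float(w_un.sum())
    return WeightField(center=center, coords=coords, weights=w_un / Z, normalizer=Z)


def _offset_distances_full(A: np.ndarray, shape: tuple[int, int], params: FilterParams):
    """Yield ((dy, dx), D2) with D2 the per-pixel squared patch distance at that offset."""
    H, W = shape
    r, rh, sh, p = params.patch.r, params.patch.half, params.search.half, params.pad
    box = np.ones((r, r))
    a0, a1 = p - rh, p + H + rh
    b0, b1 = p - rh, p + W + rh
    for dy in range(-sh, sh + 1):
        for dx in range(-sh, sh + 1):
            diff = A[a0:a1, b0:b1] - A[a0 + dy : a1 + dy, b0 + dx : b1 + dx]
            D2 = ndi.correlate(diff * diff, box, mode="constant")[rh : rh + H, rh : rh + W]
            yield (dy, dx), D2


def _offset_distances_dct(A: np.ndarray, shape: tuple[int, int], params: FilterParams):
    """As above but in the ``d``-dimensional DCT subspace, via coefficient maps."""
    H, W = shape
    sh, p = params.search.half, params.pad
    d = params.d if params.d is not None else params.patch.M
    basis = dct_basis(params.patch.r)[:d]
    # coeff_maps[k][y, x] = k-th zigzag DCT coefficient of the patch centred
    # at padded coordinate (y, x); valid wherever the patch is in bounds.
    coeff_maps = np.stack([ndi.correlate(A, b, mode="constant") for b in basis])
    core = coeff_maps[:, p : p + H, p : p + W]
    for dy in range(-sh, sh + 1):
        for dx in range(-sh, sh + 1):
            diff = core - coeff_maps[:, p + dy : p + dy + H, p + dx : p + dx + W]
            yield (dy, dx), np.einsum("kij,kij->ij", diff, diff)


def filter_image(noisy: np.ndarray, params: FilterParams) -> DenoiseResult:
    """Denoise a magnitude image with the estimator selected by ``params``.

    The image is mirror-padded so every pixel has a full search window; the
    output is therefore defined on the original grid with no border strip.
    For the unbiased methods the Rician bias correction of :func:`unbias` is
    applied pixelwise after averaging.
    """
    noisy = as_image(noisy)
    if np.any(noisy < 0):
        raise ValueError("magnitude image must be nonnegative")
    H, W = noisy.shape
    p = params.pad
    A = pad_reflect(noisy, p)
    offsets = (_offset_distances_dct if params.uses_dct else _offset_distances_full)(
        A, (H, W), params
    )
    h2 = params.h * params.h
    num = np.zeros((H, W))
    Z = np.zeros((H, W))
    w_center = None
    w_off_max = None
    for (dy, dx), D2 in offsets:
        w = np.exp(-D2 / h2)
        shifted = A[p + dy : p + dy + H, p + dx : p + dx + W]
        if params.center_weight == "max":
            if dy == 0 and dx == 0:
                w_center = shifted  # defer the centre contribution
                continue
            w_off_max = w if w_off_max is None else np.maximum(w_off_max, w)
        num += w * shifted
        Z += w
    if params.center_weight == "max":
        num += w_off_max * w_center
        Z += w_off_max
    denoised = num / Z
    if params.unbiased:
        denoised = unbias(denoised, params.sigma)
    return DenoiseResult(denoised=denoised, residual=noisy - denoised, params=params)


def weight_map(
    image: np.ndarray,
    center: tuple[int, int],
    params: FilterParams,
    log_scale: bool = False,
) -> np.ndarray:
    """The ``S x S`` image of one pixel's normalised weights.

    ``image`` is unpadded and ``center`` a coordinate of it; padding is
    applied internally.  With ``log_scale`` the natural log of the weights
    is returned (the usual display convention, since weights span many
    orders of magnitude).
    """
    image = as_image(image)
    p = params.pad
    A = pad_reflect(image, p)
    c = (center[0] + p, center[1] + p)
    field = (weights_dct if params.uses_dct else weights_full)(A, c, params)
    w = field.as_window(params.search.S)
    if log_scale:
        with np.errstate(divide="ignore"):
            return np.log(w)
    return w
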