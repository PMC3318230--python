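"""Orthonormal 2-D DCT of patches, zigzag ordering, and subspace distances.

The transform is the type-II DCT with orthonormal scaling,

    C(m, n) = a(m) a(n) sum_{x,y} p(x, y)
              cos[pi (2x+1) m / (2r)] cos[pi (2y+1) n / (2r)],

with ``a(0) = sqrt(1/r)`` and ``a(m) = sqrt(2/r)`` otherwise, so Parseval's
identity holds exactly: the squared Euclidean distance between two patches
equals the squared distance between their full coefficient vectors.  That
identity is what makes the DCT-subspace filter with ``d = M`` collapse to
plain nonlocal means.

Coefficients are ordered by the JPEG zigzag scan: anti-diagonals of
increasing spatial frequency, starting with the step from ``(0, 0)`` to
``(0, 1)``, alternating direction.  The leading ``d`` entries of that order
span the low-frequency subspace in which patch similarity is measured.
"""

from __future__ import annotations

import numpy as np
import scipy.fft

__all__ = [
    "dct2",
    "idct2",
    "zigzag_order",
    "zigzag_scan",
    "patch_to_coeffs",
    "subspace_distance",
    "dct_basis",
    "reconstruct_topk",
]


def _check_square(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be a square 2-D matrix, got shape {a.shape}")
    return a


def dct2(patch: np.ndarray) -> np.ndarray:
    """Orthonormal 2-D DCT-II of a square patch."""
    patch = _check_square(patch, "patch")
    if not np.all(np.isfinite(patch)):
        raise ValueError("patch contains non-finite values")
    return scipy.fft.dctn(patch, type=2, norm="ortho")


def idct2(coeffs: np.ndarray) -> np.ndarray:
    """Inverse of :func:`dct2` (orthonormal 2-D DCT-III)."""
    coeffs = _check_square(coeffs, "coeffs")
    return scipy.fft.idctn(coeffs, type=2, norm="ortho")


def zigzag_scan(height: int, width: int) -> list[tuple[int, int]]:
    """Zigzag traversal of an ``height x width`` grid.

    Walks anti-diagonals ``m + n = s`` for increasing ``s``, alternating
    direction so that the first step goes to ``(0, 1)``.
    """
    if height < 1 or width < 1:
        raise ValueError("grid sides must be >= 1")
    order: list[tuple[int, int]] = []
    for s in range(height + width - 1):
        diag = [(m, s - m) for m in range(max(0, s - width + 1), min(height - 1, s) + 1)]
        if s % 2 == 0:
            diag.reverse()
        order.extend(diag)
    return order


def zigzag_order(r: int) -> list[tuple[int, int]]:
    """JPEG-style zigzag order of the ``r x r`` coefficient grid."""
    if r < 1:
        raise ValueError(f"side length must be >= 1, got {r}")
    return zigzag_scan(r, r)


def patch_to_coeffs(patch: np.ndarray) -> np.ndarray:
    """DCT coefficients of a patch flattened in zigzag order (length ``r*r``)."""
    C = dct2(patch)
    order = zigzag_order(C.shape[0])
    rows, cols = zip(*order)
    return C[rows, cols]


def subspace_distance(a: np.ndarray, b: np.ndarray, d: int) -> float:
    """Squared Euclidean distance over the first ``d`` zigzag coefficients.

    With ``d = M`` this equals the full squared patch distance by Parseval.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"coefficient vectors differ in length: {a.shape} vs {b.shape}")
    if not 1 <= d <= a.size:
        raise ValueError(f"d must be in [1, {a.size}], got {d}")
    diff = a[:d] - b[:d]
    return float(diff @ diff)


def dct_basis(r: int) -> np.ndarray:
    """Orthonormal DCT basis patches in zigzag order, shape ``(r*r, r, r)``.

    ``basis[k]`` is the patch whose inner product with an image patch gives
    the k-th zigzag coefficient; used to compute per-pixel coefficient maps
    by correlation.
    """
    x = np.arange(r)
    cos = np.cos(np.pi * (2 * x[None, :] + 1) * np.arange(r)[:, None] / (2 * r))
    alpha = np.full(r, np.sqrt(2.0 / r))
    alpha[0] = np.sqrt(1.0 / r)
    rows1d = alpha[:, None] * cos  # rows1d[m, x]
    order = zigzag_order(r)
    return np.stack([np.outer(rows1d[m], rows1d[n]) for m, n in order])


def reconstruct_topk(image: np.ndarray, fraction: float) -> np.ndarray:
    """Reconstruct an image from its leading DCT coefficients.

    The whole image is transformed as a single block; the first
    ``round(fraction * Q)`` coefficients in zigzag order are kept, the rest
    zeroed, and the inverse transform applied.  Demonstrates the energy
    compaction of the DCT: a small low-frequency fraction reconstructs a
    natural image with low error.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    C = scipy.fft.dctn(image, type=2, norm="ortho")
    q = image.size
    keep = min(q, max(1, int(np.floor(fraction * q + 0.5))))
    order = zigzag_scan(*image.shape)
    mask = np.zeros(image.shape, dtype=bool)
    rows, cols = zip(*order[:keep])
    mask[rows, cols] = True
    return scipy.fft.idctn(np.where(mask, C, 0.0), type=2, norm="ortho")
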