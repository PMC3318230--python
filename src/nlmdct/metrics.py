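"""Quantitative denoising evaluation: MSE, PSNR and residual images.

PSNR follows the convention used throughout the experiments here:
``PSNR = 10 log10(Max^2 / MSE)`` with ``Max`` the maximum intensity over the
*union* of the clean and noisy images (not a fixed 255), and MSE measured
between the clean reference and the estimate.  A fixed ``Max`` can be
supplied for cross-tool comparison.  A perfect estimate yields an infinite
PSNR, reported as ``math.inf`` rather than an error so parameter sweeps
never crash on degenerate fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .image import as_image

__all__ = ["MetricRecord", "mse", "psnr", "evaluate", "residual"]


@dataclass(frozen=True)
class MetricRecord:
    """One evaluation: MSE (intensity^2), PSNR (dB; inf if exact), and the Max used."""

    mse: float
    psnr: float
    max_used: float

    def as_dict(self) -> dict:
        return asdict(self)


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b = as_image(a), as_image(b)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    return a, b


def mse(reference: np.ndarray, estimate: np.ndarray) -> float:
    """Mean squared error ``(1/Q) sum (u - u_hat)^2``."""
    reference, estimate = _check_same_shape(reference, estimate)
    diff = reference - estimate
    return float(np.mean(diff * diff))


def psnr(
    clean: np.ndarray,
    estimate: np.ndarray,
    noisy: np.ndarray | None = None,
    max_value: float | None = None,
) -> float:
    """Peak signal-to-noise ratio in dB.

    ``Max`` is ``max_value`` when given, otherwise the maximum over the
    clean image and (when supplied) the noisy image.  Returns ``math.inf``
    when the estimate is exact.
    """
    return evaluate(clean, estimate, noisy, max_value).psnr


def evaluate(
    clean: np.ndarray,
    estimate: np.ndarray,
    noisy: np.ndarray | None = None,
    max_value: float | None = None,
) -> MetricRecord:
    """MSE and PSNR of ``estimate`` against ``clean`` as a :class:`MetricRecord`."""
    clean, estimate = _check_same_shape(clean, estimate)
    if max_value is not None:
        peak = float(max_value)
    else:
        peak = float(clean.max())
        if noisy is not None:
            noisy_arr, _ = _check_same_shape(noisy, clean)
            peak = max(peak, float(noisy_arr.max()))
    if peak <= 0:
        raise ValueError(f"Max must be positive, got {peak}")
    err = mse(clean, estimate)
    value = math.inf if err == 0 else 10.0 * math.log10(peak * peak / err)
    return MetricRecord(mse=err, psnr=value, max_used=peak)


def residual(noisy: np.ndarray, denoised: np.ndarray) -> np.ndarray:
    """Residual image ``noisy - denoised`` (signed).

    Used to check visually that no anatomy was removed: a good residual
    looks like pure noise.
    """
    noisy, denoised = _check_same_shape(noisy, denoised)
    return noisy - denoised
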