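"""Rician noise simulation and noise-level estimation for magnitude MR images.

A magnitude MR image is the modulus of a complex signal whose real and
imaginary channels carry independent Gaussian noise of standard deviation
``sigma``.  The simulator reproduces that construction:

    v(i) = sqrt( (u(i) + n1(i))^2 + n2(i)^2 ),   n1, n2 ~ N(0, sigma),

so the noise in ``v`` is Rician.  The squared magnitude then carries a
signal-independent bias, ``E[v^2] = u^2 + 2 sigma^2``, which is what the
unbiased filters subtract and what the background estimator inverts: in
signal-free regions (``u = 0``), ``sigma = sqrt(E[v^2] / 2)``.

Noise levels follow the percent-of-brightest-tissue convention: level L%
means ``sigma = (L/100) * t`` where ``t`` is the brightest tissue intensity
(150 for the T1-weighted, 250 for the T2-weighted and 255 for the
PD-weighted reference phantoms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import as_image

__all__ = [
    "NoiseSpec",
    "sigma_from_level",
    "add_rician",
    "estimate_sigma_background",
    "default_background_mask",
]


def sigma_from_level(level_percent: float, t: float) -> float:
    """Gaussian channel sigma for a noise level given in percent of ``t``."""
    if t <= 0:
        raise ValueError(f"brightest-tissue value t must be positive, got {t}")
    if level_percent < 0:
        raise ValueError(f"noise level must be nonnegative, got {level_percent}")
    return (level_percent / 100.0) * t


@dataclass(frozen=True)
class NoiseSpec:
    """Noise level as percent of the brightest tissue ``t``, plus a seed."""

    level_percent: float
    t: float
    seed: int = 0

    def __post_init__(self) -> None:
        sigma_from_level(self.level_percent, self.t)  # validates

    @property
    def sigma(self) -> float:
        return sigma_from_level(self.level_percent, self.t)


def add_rician(clean: np.ndarray, sigma: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Corrupt a nonnegative image with Rician noise of channel sigma ``sigma``.

    The real-channel noise field is drawn before the imaginary one, each in
    row-major order from one ``numpy`` Generator seeded by ``seed``, so the
    output is bit-reproducible for a given seed.  ``sigma = 0`` returns the
    input unchanged.
    """
    clean = as_image(clean)
    if np.any(clean < 0):
        raise ValueError("clean magnitude image must be nonnegative")
    if sigma < 0:
        raise ValueError(f"sigma must be nonnegative, got {sigma}")
    if sigma == 0:
        return clean.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, clean.shape)
    n2 = rng.normal(0.0, sigma, clean.shape)
    return np.hypot(clean + n1, n2)


def estimate_sigma_background(
    noisy: np.ndarray, background_mask: np.ndarray, min_pixels: int = 100
) -> float:
    """Estimate sigma from signal-free background pixels.

    Uses the second moment of the squared magnitude: where ``u = 0`` the
    magnitude is Rayleigh with ``E[v^2] = 2 sigma^2``, so
    ``sigma_hat = sqrt(mean(v^2) / 2)`` over the masked pixels.
    """
    noisy = as_image(noisy)
    mask = np.asarray(background_mask, dtype=bool)
    if mask.shape != noisy.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {noisy.shape}")
    n = int(mask.sum())
    if n < min_pixels:
        raise ValueError(f"background mask selects only {n} pixels (< {min_pixels})")
    v = noisy[mask]
    return float(np.sqrt(np.mean(v * v) / 2.0))


def default_background_mask(
    noisy: np.ndarray, border: int = 10, threshold: float | None = None
) -> np.ndarray:
    """Convenience background mask: a border frame, optionally intensity-gated.

    Selects a frame of ``border`` pixels around the image edge and, when
    ``threshold`` is given, keeps only pixels below it — a crude but
    serviceable proxy for air around the imaged object.  For simulated
    phantoms prefer the exact mask from :func:`nlmdct.phantom.background_mask`.
    """
    noisy = as_image(noisy)
    if border < 1:
        raise ValueError("border must be >= 1")
    mask = np.zeros(noisy.shape, dtype=bool)
    mask[:border, :] = mask[-border:, :] = True
    mask[:, :border] = mask[:, -border:] = True
    if threshold is not None:
        mask &= noisy < threshold
    return mask
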