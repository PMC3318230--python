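"""Deterministic piecewise-constant tissue phantoms.

The generator paints analytic shapes (ellipse inequalities and axis-aligned
rectangles) in a declared z-order on a zero background, emulating the
structure of simulated brain slices: a head outline, nested tissue regions
of distinct constant intensities, and small bright/dark structures.  Shapes
are placed in fractional canvas coordinates so the same spec renders at any
resolution; no file, raster or random number is involved, so a spec renders
bit-identically everywhere.

The background is exactly zero, which makes the phantoms directly usable
with the signal-free background sigma estimator, and the brightest declared
tissue value ``t`` anchors the percent noise-level convention.  Presets
named after the standard T1/T2/PD reference images use the matching
brightest-tissue values t = 150, 250 and 255 on a 181 x 217 canvas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Ellipse", "Rect", "PhantomSpec", "make_phantom", "background_mask", "brain_phantom"]


@dataclass(frozen=True)
class Ellipse:
    """Filled ellipse in fractional canvas coordinates (cy, cx, ry, rx in [0, 1])."""

    cy: float
    cx: float
    ry: float
    rx: float

    def mask(self, height: int, width: int) -> np.ndarray:
        y = (np.arange(height) + 0.5) / height
        x = (np.arange(width) + 0.5) / width
        dy = (y[:, None] - self.cy) / self.ry
        dx = (x[None, :] - self.cx) / self.rx
        return dy * dy + dx * dx <= 1.0

    def fits(self) -> bool:
        return (
            0 <= self.cy - self.ry
            and self.cy + self.ry <= 1
            and 0 <= self.cx - self.rx
            and self.cx + self.rx <= 1
        )


@dataclass(frozen=True)
class Rect:
    """Filled axis-aligned rectangle in fractional coordinates (top, left, h, w)."""

    top: float
    left: float
    h: float
    w: float

    def mask(self, height: int, width: int) -> np.ndarray:
        y = (np.arange(height) + 0.5) / height
        x = (np.arange(width) + 0.5) / width
        iny = (y >= self.top) & (y <= self.top + self.h)
        inx = (x >= self.left) & (x <= self.left + self.w)
        return iny[:, None] & inx[None, :]

    def fits(self) -> bool:
        return 0 <= self.top and self.top + self.h <= 1 and 0 <= self.left and self.left + self.w <= 1


@dataclass(frozen=True)
class PhantomSpec:
    """Canvas size plus (intensity, shape) layers painted in order.

    The declared brightest intensity is the phantom's ``t``; the invariant
    ``max(image) == t`` holds as long as the brightest layer is not fully
    overpainted by later layers (the presets guarantee it).
    """

    height: int = 181
    width: int = 217
    tissue_levels: tuple = ()
    background_value: float = 0.0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("canvas sides must be positive")
        if not self.tissue_levels:
            return
        for intensity, shape in self.tissue_levels:
            if intensity < 0:
                raise ValueError(f"tissue intensity must be nonnegative, got {intensity}")
            if not shape.fits():
                raise ValueError(f"shape {shape} exceeds the canvas")

    @property
    def t(self) -> float:
        """Brightest declared tissue intensity."""
        if not self.tissue_levels:
            raise ValueError("phantom spec declares no tissue")
        return max(intensity for intensity, _ in self.tissue_levels)


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render the phantom: shapes painted over a zero background in z-order."""
    img = np.full((spec.height, spec.width), float(spec.background_value))
    for intensity, shape in spec.tissue_levels:
        img[shape.mask(spec.height, spec.width)] = float(intensity)
    return img


def background_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean grid, true exactly where no shape was painted."""
    painted = np.zeros((spec.height, spec.width), dtype=bool)
    for _, shape in spec.tissue_levels:
        painted |= shape.mask(spec.height, spec.width)
    return ~painted


#: Brightest-tissue intensities of the named presets.
PRESET_T = {"T1": 150.0, "T2": 250.0, "PD": 255.0}


def brain_phantom(preset: str = "T1", height: int = 181, width: int = 217) -> PhantomSpec:
    """Brain-like phantom spec: head outline, tissue ring, ventricles, lesions.

    ``preset`` selects the brightest-tissue value ``t`` (T1: 150, T2: 250,
    PD: 255); relative layer intensities are fractions of ``t`` so the
    histogram support is {0} plus a handful of distinct tissue values.
    """
    key = preset.upper()
    if key not in PRESET_T:
        raise ValueError(f"unknown preset {preset!r}; expected one of {sorted(PRESET_T)}")
    t = PRESET_T[key]
    layers = (
        (0.45 * t, Ellipse(0.50, 0.50, 0.42, 0.40)),   # head / outer tissue
        (0.70 * t, Ellipse(0.50, 0.50, 0.34, 0.31)),   # cortical ring
        (0.55 * t, Ellipse(0.52, 0.50, 0.26, 0.23)),   # deep tissue
        (0.25 * t, Ellipse(0.44, 0.42, 0.09, 0.05)),   # left ventricle
        (0.25 * t, Ellipse(0.44, 0.58, 0.09, 0.05)),   # right ventricle
        (1.00 * t, Ellipse(0.68, 0.50, 0.07, 0.09)),   # brightest structure
        (0.85 * t, Rect(0.28, 0.46, 0.06, 0.08)),      # small bright lesion
        (0.40 * t, Rect(0.60, 0.28, 0.05, 0.05)),      # small dark lesion
    )
    return PhantomSpec(height=height, width=width, tissue_levels=layers)
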