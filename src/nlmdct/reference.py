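"""Brute-force reference implementations of the filters.

Direct per-pixel double loops that transcribe the estimator definitions
term by term, with no shared code path with the vectorised
:func:`nlmdct.filters.filter_image`.  Orders of magnitude slower; intended
for validating the optimised filters on small images.
"""

from __future__ import annotations

import math

import numpy as np

from .dct import patch_to_coeffs
from .filters import DenoiseResult, unbias
from .image import FilterParams, as_image, pad_reflect


def filter_image_naive(noisy: np.ndarray, params: FilterParams) -> DenoiseResult:
    """Direct-sum evaluation of the selected estimator (small images only)."""
    noisy = as_image(noisy)
    H, W = noisy.shape
    rh, sh, p = params.patch.half, params.search.half, params.pad
    A = pad_reflect(noisy, p)
    use_dct = params.uses_dct
    d = params.d if params.d is not None else params.patch.M

    def descriptor(y, x):
        patch = A[y - rh : y + rh + 1, x - rh : x + rh + 1]
        return patch_to_coeffs(patch)[:d] if use_dct else patch

    out = np.empty((H, W))
    for y in range(H):
        for x in range(W):
            cy, cx = y + p, x + p
            di = descriptor(cy, cx)
            num = 0.0
            Z = 0.0
            w_self_pos = None
            terms = []
            for dy in range(-sh, sh + 1):
                for dx in range(-sh, sh + 1):
                    jy, jx = cy + dy, cx + dx
                    diff = di - descriptor(jy, jx)
                    D2 = float((diff * diff).sum())
                    w = math.exp(-D2 / (params.h * params.h))
                    terms.append([w, A[jy, jx]])
                    if dy == 0 and dx == 0:
                        w_self_pos = len(terms) - 1
            if params.center_weight == "max" and len(terms) > 1:
                w_max = max(w for k, (w, _) in enumerate(terms) if k != w_self_pos)
                terms[w_self_pos][0] = w_max
            for w, v in terms:
                num += w * v
                Z += w
            out[y, x] = num / Z
    if params.unbiased:
        out = unbias(out, params.sigma)
    return DenoiseResult(denoised=out, residual=noisy - out, params=params)
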