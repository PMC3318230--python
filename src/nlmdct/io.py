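"""Reading and writing 2-D grayscale images (PGM/PNG/TIFF/NIfTI).

Pixels are promoted to ``float64`` on load and never rescaled: a 16-bit
file with maximum 4095 loads as values up to 4095.0.  TIFF and NIfTI
round-trip floating point losslessly; PGM and PNG store integers, so
writing to them rounds and picks 8- or 16-bit depth by range.
"""

from __future__ import annotations

import os

import numpy as np

from .image import as_image

__all__ = ["read_image", "write_image"]

_NIFTI_EXT = (".nii", ".nii.gz")
_RASTER_EXT = (".pgm", ".png", ".tif", ".tiff")


def _ext(path: str) -> str:
    lower = str(path).lower()
    for e in _NIFTI_EXT:
        if lower.endswith(e):
            return e
    return os.path.splitext(lower)[1]


def read_image(path: str, slice_index: int | None = None) -> np.ndarray:
    """Load a 2-D grayscale image as a nonnegative float64 array.

    NIfTI volumes require ``slice_index`` (a plane along the last axis);
    2-D NIfTI files ignore it.  Multi-channel rasters are accepted only when
    all channels are identical (gray stored as RGB).
    """
    ext = _ext(path)
    if ext in _NIFTI_EXT:
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj)
        data = np.squeeze(data)
        if data.ndim == 3:
            if slice_index is None:
                raise ValueError(
                    f"{path}: NIfTI volume has {data.shape[2]} slices; a slice index is required"
                )
            if not 0 <= slice_index < data.shape[2]:
                raise ValueError(f"{path}: slice index {slice_index} out of range")
            data = data[:, :, slice_index]
        elif data.ndim != 2:
            raise ValueError(f"{path}: cannot interpret NIfTI data of shape {data.shape}")
    elif ext in _RASTER_EXT:
        import imageio.v3 as iio

        data = np.asarray(iio.imread(str(path)))
        if data.ndim == 3:
            if data.shape[2] in (3, 4) and np.all(data[..., :3] == data[..., :1]):
                data = data[..., 0]
            else:
                raise ValueError(f"{path}: expected a grayscale image, got shape {data.shape}")
    else:
        raise ValueError(f"{path}: unsupported image format {ext!r}")
    img = as_image(data)
    if np.any(img < 0):
        raise ValueError(f"{path}: magnitude image contains negative values")
    return img


def write_image(path: str, image: np.ndarray) -> None:
    """Write an image, choosing encoding by extension.

    ``.tif``/``.tiff`` and ``.nii`` store float64 (lossless round-trip);
    ``.pgm``/``.png`` round to integers, 8-bit when the range allows and
    16-bit otherwise.
    """
    image = as_image(image)
    ext = _ext(path)
    if ext in _NIFTI_EXT:
        import nibabel as nib

        nib.save(nib.Nifti1Image(image.astype(np.float64), affine=np.eye(4)), str(path))
    elif ext in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), image.astype(np.float64))
    elif ext in (".pgm", ".png"):
        import imageio.v3 as iio

        quant = np.rint(np.clip(image, 0, None))
        dtype = np.uint8 if quant.max() <= 255 else np.uint16
        if dtype is np.uint16 and quant.max() > 65535:
            raise ValueError(f"{path}: intensities exceed 16-bit range; use TIFF or NIfTI")
        iio.imwrite(str(path), quant.astype(dtype))
    else:
        raise ValueError(f"{path}: unsupported image format {ext!r}")
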