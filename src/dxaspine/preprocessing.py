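"""Image container and height standardisation.

Whole-body DXA scans arrive at scanner-dependent sizes; the first pipeline
stage rescales every image to a common height while preserving the aspect
ratio, so that all downstream pixel-unit parameters have a fixed meaning.

Coordinate convention throughout the package: 0-based ``(row, column)``
indices, row 0 at the top of the image (the head end of a supine scan).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import InvalidInputError

_PNG_MAX = 65535.0


@dataclass
class DxaImage:
    """A 2-D grayscale DXA-like image.

    Parameters
    ----------
    pixels
        Non-negative float intensities, shape ``(height_px, width_px)``.
        The nominal intensity scale is [0, 1] but values above 1 are legal.
    pixel_size_mm
        Optional physical pixel pitch; carried through untouched.
    image_id
        Opaque identifier used in records and log lines.
    """

    pixels: np.ndarray
    pixel_size_mm: float | None = None
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InvalidInputError("DxaImage requires a non-empty 2-D pixel grid")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise InvalidInputError("intensities must be finite and non-negative")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


def standardize_height(image: DxaImage, target_height_px: int) -> DxaImage:
    """Isotropically rescale ``image`` to ``target_height_px`` rows.

    The width becomes ``round(width * target/height)``, so the aspect ratio
    is preserved to within one pixel of rounding.  Bilinear interpolation is
    used in both directions.  Rescaling to the current height is the
    identity.
    """
    if target_height_px < 2:
        raise InvalidInputError("target_height_px must be >= 2")
    h, w = image.pixels.shape
    if target_height_px == h:
        return image
    out_w = max(1, round(w * target_height_px / h))
    # skimage.resize is bilinear at order=1; no anti-alias smoothing on
    # upscale, gaussian pre-filter on downscale per its default.
    from skimage.transform import resize

    out = resize(
        image.pixels,
        (target_height_px, out_w),
        order=1,
        mode="edge",
        anti_aliasing=target_height_px < h,
        preserve_range=True,
    )
    scale = h / target_height_px
    return DxaImage(
        pixels=np.clip(out, 0.0, None),
        pixel_size_mm=None if image.pixel_size_mm is None else image.pixel_size_mm * scale,
        image_id=image.image_id,
    )


def load_image(path: str | Path, image_id: str | None = None) -> DxaImage:
    """Read a grayscale PNG or TIFF into a [0, 1]-scaled :class:`DxaImage`."""
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:  # RGB(A) saved by other tools: average channels
        arr = arr[..., :3].mean(axis=2)
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        arr = arr / (_PNG_MAX if arr.max() > 255 else 255.0)
    return DxaImage(pixels=arr, image_id=image_id or path.stem)


def save_image(image: DxaImage, path: str | Path) -> None:
    """Write as 16-bit grayscale PNG/TIFF (intensities clipped to [0, 1])."""
    arr = np.clip(image.pixels, 0.0, 1.0)
    Image.fromarray((arr * _PNG_MAX).astype(np.uint16)).save(Path(path))
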