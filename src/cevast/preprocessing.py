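"""Frame pre-processing: center crop, geometric-mean grayscale, position stamp.

Capsule frames are reduced to a square central crop, collapsed to a single
channel via the per-pixel geometric mean of R, G and B (which, unlike a
luma-weighted mean, zeroes any pixel with a dead channel and compresses
specular highlights), and tagged with the frame's normalized SI position
encoded as an 8-bit value written into a reserved corner block so that the
position survives into the raster itself.

Conventions (the upstream description leaves these open; fixed here):

* Center crop; for odd margins the extra pixel goes to the bottom/right.
* Stamp block: top-left ``16 x 16`` pixels, value ``round(255 p)`` with
  round-half-up.
* Grayscale is computed in floating point; rounding to a storage depth
  happens only on export.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "STAMP_BLOCK",
    "crop_center",
    "to_grayscale_geomean",
    "encode_position",
    "decode_position",
    "preprocess_frame",
]

#: side length of the square corner block carrying the position code
STAMP_BLOCK = 16


def crop_center(image: np.ndarray, size: int) -> np.ndarray:
    """Central ``size x size`` crop (leading two axes).

    Raises ``ValueError`` if the image is smaller than ``size`` in either
    spatial dimension.
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    if h < size or w < size:
        raise ValueError(f"image {h}x{w} smaller than crop size {size}")
    top = (h - size) // 2
    left = (w - size) // 2
    return img[top : top + size, left : left + size]


def to_grayscale_geomean(rgb: np.ndarray) -> np.ndarray:
    """Per-pixel geometric mean ``(R*G*B)^(1/3)`` as float64.

    Any zero channel yields a zero pixel.  Raises ``ValueError`` unless the
    last axis has exactly 3 channels.
    """
    img = np.asarray(rgb, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 raster")
    return np.cbrt(img[..., 0] * img[..., 1] * img[..., 2])


def _stamp_code(p: float) -> int:
    # round-half-up on the 8-bit scale
    return int(np.floor(255.0 * p + 0.5))


def encode_position(frame: np.ndarray, p: float, block: int = STAMP_BLOCK) -> np.ndarray:
    """Write the 8-bit position code into the top-left corner block.

    Returns a copy; the rest of the raster is unchanged.  ``p`` must lie in
    [0, 1].
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"position must be in [0, 1], got {p}")
    out = np.array(frame, dtype=float, copy=True)
    out[:block, :block, ...] = _stamp_code(p)
    return out


def decode_position(frame: np.ndarray, block: int = STAMP_BLOCK) -> float:
    """Recover ``p = code / 255`` from the corner stamp.

    Raises ``ValueError`` if the corner block is not constant (no stamp).
    """
    corner = np.asarray(frame, dtype=float)[:block, :block, ...]
    if corner.size == 0:
        raise ValueError("frame too small to carry a stamp block")
    v = corner.flat[0]
    if not np.allclose(corner, v, atol=1e-9):
        raise ValueError("corner block is not constant; no position stamp found")
    return float(v) / 255.0


def preprocess_frame(
    rgb: np.ndarray, p: float | None = None, crop: int | None = None
) -> np.ndarray:
    """Full pipeline: optional center crop, grayscale, optional stamp."""
    img = np.asarray(rgb)
    if crop is not None:
        img = crop_center(img, crop)
    gray = to_grayscale_geomean(img)
    if p is not None:
        gray = encode_position(gray, p)
    return gray
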