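"""Dihedral test-time ensembling of frame scores.

A square frame has eight orientations — the dihedral group of the square:
identity, rotations by 90/180/270 degrees, horizontal and vertical flips,
and the two flip+rotation compositions (the diagonal transposes).  Scoring
all eight and combining with inverse-squared-error weights reduces the
effective per-frame noise while the spread of the eight predictions gives a
model-free second estimate of per-frame uncertainty.
"""

from __future__ import annotations

import numpy as np

from .scorer import FrameScore

__all__ = ["dihedral_orientations", "ensemble_score", "score_frame_ensembled"]


def dihedral_orientations(image: np.ndarray) -> list[np.ndarray]:
    """The 8 dihedral transforms of a square raster.

    Order: identity, rot90, rot180, rot270, then the horizontal flip
    followed by the same four rotations (covering both flips and the two
    transposes).  Raises ``ValueError`` for non-square rasters.
    """
    img = np.asarray(image)
    if img.shape[0] != img.shape[1]:
        raise ValueError(f"raster must be square, got {img.shape[0]}x{img.shape[1]}")
    flipped = img[:, ::-1]
    return [np.rot90(img, k) for k in range(4)] + [np.rot90(flipped, k) for k in range(4)]


def ensemble_score(scores) -> FrameScore:
    """Combine 8 per-orientation scores by inverse-squared-error weighting.

    ``w_i = (1 / e_i)^2``; the ensembled severity and error are the
    weighted means of the individual severities and errors, and
    ``orientation_spread`` is the population standard deviation of the 8
    severity predictions.
    """
    scores = list(scores)
    if len(scores) != 8:
        raise ValueError(f"expected 8 orientation scores, got {len(scores)}")
    y = np.array([s.severity for s in scores], dtype=float)
    e = np.array([s.error for s in scores], dtype=float)
    if np.any(e <= 0):
        raise ValueError("predicted errors must be positive (floored upstream)")
    w = 1.0 / e**2
    return FrameScore(
        severity=float(np.sum(w * y) / np.sum(w)),
        error=float(np.sum(w * e) / np.sum(w)),
        orientation_spread=float(np.std(y)),  # population form (divide by 8)
    )


def score_frame_ensembled(model, frame) -> FrameScore:
    """Score a frame in all 8 orientations and combine."""
    img = frame.image if hasattr(frame, "image") else np.asarray(frame)
    return ensemble_score(model.score_frame(o) for o in dihedral_orientations(img))
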