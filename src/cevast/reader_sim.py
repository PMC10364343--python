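"""Simulated expert readers scoring frames on the ordinal 0-3 scale.

An expert viewing a frame perceives the underlying severity corrupted by an
individual additive Gaussian deviation (optionally biased), then reports
the nearest integer grade, clipped to the scale: 0 no disease, 1 mild,
2 moderate, 3 severe.  Reads are organized the way the unbiased scoring
protocol presents them: sessions of 5-10 videos with all frames shuffled
together, a fixed number of scored frames per video (default 60).

The single free parameter — the reader's noise standard deviation — is
pinned by :func:`calibrate_reader_noise` so that the simulated mean
absolute error of one reader's discretized score against the mean score of
a three-reader panel matches a target (the reference panel value is 0.1875
severity units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReaderModel",
    "ReadingSession",
    "CalibrationError",
    "simulate_reader_scores",
    "calibrate_reader_noise",
    "build_sessions",
    "DEFAULT_FRAMES_PER_VIDEO",
]

DEFAULT_FRAMES_PER_VIDEO = 60


class CalibrationError(RuntimeError):
    """Raised when a target reader error is unreachable."""


@dataclass(frozen=True)
class ReaderModel:
    """One simulated expert: additive bias and Gaussian noise pre-rounding."""

    reader_id: str = "reader1"
    bias: float = 0.0
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def simulate_reader_scores(profile, positions, reader: ReaderModel) -> np.ndarray:
    """Integer 0-3 scores for ``positions``: ``round(clip(s + bias + noise, 0, 3))``.

    ``profile`` is anything callable as severity(p) (a
    :class:`~cevast.synthetic_data.SeverityProfile`) or an array of true
    severities matching ``positions``.  Seeded by the reader's seed.
    """
    positions = np.asarray(positions, dtype=float)
    if np.any((positions < 0) | (positions > 1)):
        raise ValueError("positions must lie in [0, 1]")
    truth = profile(positions) if callable(profile) else np.asarray(profile, dtype=float)
    rng = np.random.default_rng(reader.seed)
    noise = rng.normal(0.0, reader.noise_sd, size=positions.shape) if reader.noise_sd > 0 else 0.0
    perceived = np.clip(truth + reader.bias + noise, 0.0, 3.0)
    return _round_half_up(perceived).astype(int)


def _panel_mae(noise_sd: float, n_sim: int, rng_seed: int) -> float:
    """MAE of reader 1's discretized score vs the 3-reader panel mean."""
    rng = np.random.default_rng(rng_seed)
    truth = rng.uniform(0.0, 3.0, size=n_sim)
    scores = np.empty((3, n_sim))
    for r in range(3):
        noise = rng.normal(0.0, noise_sd, size=n_sim)
        scores[r] = _round_half_up(np.clip(truth + noise, 0.0, 3.0))
    panel_mean = scores.mean(axis=0)
    return float(np.abs(scores[0] - panel_mean).mean())


def calibrate_reader_noise(
    target_mae: float = 0.1875,
    n_sim: int = 200_000,
    seed: int = 0,
    tol: float = 0.01,
) -> float:
    """Noise SD at which one reader's MAE vs the 3-reader mean hits the target.

    Bisection on the noise SD using common random numbers, so the simulated
    MAE is a deterministic monotone function of the SD.  Raises
    :class:`CalibrationError` if the target lies outside the reachable
    range (zero at zero noise, saturating as scores pin to the scale ends).
    """
    if target_mae <= 0:
        raise CalibrationError("target MAE must be positive")
    lo, hi = 0.0, 6.0
    if _panel_mae(hi, n_sim, seed) < target_mae:
        raise CalibrationError(
            f"target MAE {target_mae} unreachable: scores are capped at the scale ends "
            f"(max simulated MAE {_panel_mae(hi, n_sim, seed):.3f})"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _panel_mae(mid, n_sim, seed) < target_mae:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * 1e-3:
            break
    return 0.5 * (lo + hi)


@dataclass
class ReadingSession:
    """One shuffled reading session covering 5-10 videos."""

    session_id: int
    video_ids: list
    frames_per_video: int
    presentation_order: list = field(default_factory=list)  # (video_id, frame_slot)


def build_sessions(
    video_ids,
    frames_per_video: int = DEFAULT_FRAMES_PER_VIDEO,
    seed: int = 0,
) -> list[ReadingSession]:
    """Partition videos into sessions of 5-10 and shuffle frame presentation.

    Session sizes are as equal as possible within [5, 10].  With fewer than
    5 videos a single undersized session is returned with a warning.  The
    presentation order interleaves all (video, frame-slot) pairs of the
    session in a seeded permutation.
    """
    video_ids = list(video_ids)
    n = len(video_ids)
    rng = np.random.default_rng(seed)
    if n == 0:
        raise ValueError("no videos")
    if n < 5:
        warnings.warn(f"only {n} videos; building a single undersized session")
        sizes = [n]
    else:
        n_sessions = int(np.ceil(n / 10))
        base = n // n_sessions
        rem = n % n_sessions
        sizes = [base + (1 if i < rem else 0) for i in range(n_sessions)]
    sessions = []
    start = 0
    for sid, size in enumerate(sizes):
        vids = video_ids[start : start + size]
        start += size
        slots = [(v, k) for v in vids for k in range(frames_per_video)]
        order = [slots[i] for i in rng.permutation(len(slots))]
        sessions.append(
            ReadingSession(
                session_id=sid,
                video_ids=vids,
                frames_per_video=frames_per_video,
                presentation_order=order,
            )
        )
    return sessions
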