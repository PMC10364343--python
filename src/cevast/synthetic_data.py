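"""Synthetic capsule-endoscopy cohorts with known ground truth.

Celiac enteropathy is typically proximal-predominant and patchy: villous
damage is worst just past the pylorus and heals distally, with
non-continuous skip regions.  This module generates per-patient severity
profiles with exactly that structure, renders textured frames whose
spatial-frequency content encodes the severity (a stand-in for the loss of
fine villous texture as atrophy progresses), and assembles whole cohorts so
that every downstream stage — scoring, ensembling, curve fitting, reader
simulation, agreement statistics — can be exercised end to end without any
clinical video.

Severity is on the 4-point ordinal scale used throughout the package:
0 = no disease, 1 = mild, 2 = moderate, 3 = severe.  Position ``p`` is the
normalized small-intestine (SI) coordinate: 0 at the last pyloric frame,
1 at the first cecal frame.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "ProfileParams",
    "SeverityProfile",
    "SyntheticFrame",
    "CohortConfig",
    "Cohort",
    "PatientRecord",
    "generate_profile",
    "render_frame",
    "texture_statistic",
    "estimate_severity_from_texture",
    "generate_cohort",
]

#: number of points in the dense latent grid used to realize patch noise
_PROFILE_GRID_N = 2048

#: fixed base seed for the texture-statistic calibration table (not a dial:
#: it only pins the oracle estimator's lookup table so it is reproducible)
_CALIBRATION_SEED = 987_654_321


@dataclass(frozen=True)
class ProfileParams:
    """Parameters of a ground-truth severity profile.

    Parameters
    ----------
    s0 : float
        Proximal baseline severity at ``p = 0``, in [0, 3].
    k : float
        Exponential decay rate of severity along the SI, ``>= 0``.
        ``k = 0`` gives a flat profile.
    a : float
        Amplitude of patchy deviations (severity units), ``>= 0``.
    corr_length : float
        Correlation length of the patchiness as a fraction of SI length,
        in (0, 1].  Small values give fine-grained skip lesions.
    """

    s0: float = 2.0
    k: float = 1.0
    a: float = 0.0
    corr_length: float = 0.2

    def validate(self) -> None:
        if not 0.0 <= self.s0 <= 3.0:
            raise ValueError(f"s0 must be in [0, 3], got {self.s0}")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if self.a < 0:
            raise ValueError(f"a must be >= 0, got {self.a}")
        if not 0.0 < self.corr_length <= 1.0:
            raise ValueError(
                f"corr_length must be in (0, 1], got {self.corr_length}"
            )


class SeverityProfile:
    """Ground-truth severity as a function of normalized SI position.

    The profile is ``clip(s0 * exp(-k p) + patch(p), 0, 3)`` where ``patch``
    is smooth correlated Gaussian noise with standard deviation ``a`` and
    correlation length ``corr_length``.  Evaluations are bitwise
    reproducible for identical ``(params, seed)``.
    """

    def __init__(self, params: ProfileParams, seed: int, patient_id: str = "p0"):
        params.validate()
        self.params = params
        self.seed = int(seed)
        self.patient_id = patient_id
        self._grid = np.linspace(0.0, 1.0, _PROFILE_GRID_N)
        if params.a > 0:
            rng = np.random.default_rng(self.seed)
            white = rng.standard_normal(_PROFILE_GRID_N)
            sigma_px = params.corr_length * (_PROFILE_GRID_N - 1)
            patch = gaussian_filter1d(white, sigma=sigma_px, mode="nearest")
            sd = patch.std()
            if sd > 0:
                patch = patch / sd
            self._patch = params.a * patch
        else:
            self._patch = np.zeros(_PROFILE_GRID_N)

    def eval(self, p):
        """Severity at position(s) ``p`` in [0, 1], clipped to [0, 3]."""
        p = np.asarray(p, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("positions must lie in [0, 1]")
        base = self.params.s0 * np.exp(-self.params.k * p)
        patch = np.interp(p, self._grid, self._patch)
        return np.clip(base + patch, 0.0, 3.0)

    __call__ = eval


def generate_profile(
    params: ProfileParams, seed: int, patient_id: str = "p0"
) -> SeverityProfile:
    """Build a :class:`SeverityProfile`; raises ``ValueError`` on bad params."""
    return SeverityProfile(params, seed, patient_id)


@dataclass
class SyntheticFrame:
    """One rendered frame of a synthetic capsule video."""

    image: np.ndarray  # H x W x 3 uint8
    position: float  # normalized SI position in [0, 1]
    true_severity: float  # in [0, 3]
    patient_id: str = "p0"
    frame_index: int = 0


# --------------------------------------------------------------------------
# Texture rendering and the severity-encoding statistic
# --------------------------------------------------------------------------
#
# Healthy mucosa shows a fine villous mosaic (high spatial frequency);
# atrophic mucosa is flat and smooth.  We emulate this with a random-phase
# texture: the amplitude spectrum is a fixed Gaussian low-pass whose width
# shrinks as severity grows (so the texture coarsens), while the Fourier
# phases are the only random ingredient.  Because the amplitude spectrum is
# deterministic, the normalized RMS roughness statistic T — computed with
# circular nearest-neighbour differences — depends on the realized phases
# only through uint8 quantization, so T is a sharp, strictly monotone
# decreasing encoding of severity.  T averages horizontal and vertical
# roughness and uses periodic differences, making it invariant under all
# eight dihedral orientations of the frame.


def _smoothing_sigma(severity) -> np.ndarray:
    """Spatial smoothing scale (pixels) encoding severity; strictly increasing."""
    return 0.6 + 0.8 * np.asarray(severity, dtype=float)


def _random_phase_field(sigma: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance random-phase field with a Gaussian amplitude spectrum."""
    white = rng.standard_normal((size, size))
    F = np.fft.fft2(white)
    F = F / np.maximum(np.abs(F), 1e-30)  # keep phases, fix amplitudes
    fx = np.fft.fftfreq(size)
    k2 = (fx[:, None] ** 2 + fx[None, :] ** 2) * (2 * np.pi) ** 2
    G = np.exp(-0.5 * sigma**2 * k2)
    G[0, 0] = 0.0  # zero mean
    fld = np.real(np.fft.ifft2(F * G))
    return fld / max(fld.std(), 1e-12)


def render_frame(true_severity: float, image_size: int = 64, seed: int = 0) -> np.ndarray:
    """Render an RGB frame whose texture encodes ``true_severity``.

    Returns an ``image_size x image_size x 3`` uint8 raster.  Rendering is
    seed-deterministic: identical arguments give identical rasters.
    """
    s = float(true_severity)
    if not 0.0 <= s <= 3.0:
        raise ValueError(f"true_severity must be in [0, 3], got {s}")
    if image_size < 8:
        raise ValueError("image_size must be >= 8")
    rng = np.random.default_rng(seed)
    fld = _random_phase_field(float(_smoothing_sigma(s)), image_size, rng)
    lum = 128.0 + 28.0 * fld
    # warm mucosal tint; per-channel gains keep the geometric mean textured
    rgb = np.stack([lum, lum * 0.80, lum * 0.62], axis=-1)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def texture_statistic(image: np.ndarray) -> float:
    """Roughness statistic T: normalized RMS circular nearest-neighbour
    difference of the grayscale.  Strictly monotone decreasing in severity;
    dihedral-invariant."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        gray = np.cbrt(img[..., 0] * img[..., 1] * img[..., 2])
    else:
        gray = img
    z = gray - gray.mean()
    sd = z.std()
    if sd <= 0:
        return 0.0
    z = z / sd
    dx = np.mean((z - np.roll(z, 1, axis=1)) ** 2)
    dy = np.mean((z - np.roll(z, 1, axis=0)) ** 2)
    return float(np.sqrt(0.5 * (dx + dy)))


_CAL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _calibration_table(image_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean T at a severity grid, for inverting T back to severity.

    Built once per image size from a fixed bank of seeded renders; cached.
    """
    if image_size not in _CAL_CACHE:
        sev = np.linspace(0.0, 3.0, 31)
        n_rep = 24
        means = np.empty_like(sev)
        for i, s in enumerate(sev):
            vals = [
                texture_statistic(
                    render_frame(s, image_size, seed=_CALIBRATION_SEED + 1000 * i + r)
                )
                for r in range(n_rep)
            ]
            means[i] = float(np.mean(vals))
        # enforce strict monotone decrease so interpolation is invertible
        means = np.minimum.accumulate(means)
        _CAL_CACHE[image_size] = (sev, means)
    return _CAL_CACHE[image_size]


def estimate_severity_from_texture(image: np.ndarray) -> float:
    """Invert the texture statistic to a severity estimate in [0, 3]."""
    img = np.asarray(image)
    size = img.shape[0]
    sev, t_mean = _calibration_table(size)
    t = texture_statistic(img)
    # t_mean is decreasing in severity; flip for np.interp
    est = np.interp(t, t_mean[::-1], sev[::-1])
    return float(np.clip(est, 0.0, 3.0))


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    Profile parameters are sampled per patient from the given ranges, which
    span the clinical spectrum from no visible enteropathy to severe
    proximal atrophy.
    """

    n_patients: int = 20
    frames_per_video: int = 60
    image_size: int = 64
    seed: int = 0
    jitter: bool = True
    s0_range: tuple[float, float] = (0.2, 3.0)
    k_range: tuple[float, float] = (0.0, 2.0)
    a_range: tuple[float, float] = (0.1, 0.5)
    corr_length_range: tuple[float, float] = (0.1, 0.3)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.frames_per_video < 2:
            raise ValueError("frames_per_video must be >= 2")


@dataclass
class PatientRecord:
    """One synthetic patient: profile plus frame positions and render seeds."""

    profile: SeverityProfile
    positions: np.ndarray
    frame_seeds: np.ndarray
    image_size: int

    @property
    def patient_id(self) -> str:
        return self.profile.patient_id

    def iter_frames(self):
        """Yield :class:`SyntheticFrame` lazily (frames can be numerous)."""
        sev = self.profile.eval(self.positions)
        for i, (p, s, sd) in enumerate(zip(self.positions, sev, self.frame_seeds)):
            yield SyntheticFrame(
                image=render_frame(float(s), self.image_size, int(sd)),
                position=float(p),
                true_severity=float(s),
                patient_id=self.patient_id,
                frame_index=i,
            )


@dataclass
class Cohort:
    config: CohortConfig
    patients: list[PatientRecord] = field(default_factory=list)

    def truth_table(self):
        """Ground-truth table: patient_id, frame_index, position, true_severity."""
        import pandas as pd

        rows = []
        for rec in self.patients:
            sev = rec.profile.eval(rec.positions)
            for i, (p, s) in enumerate(zip(rec.positions, sev)):
                rows.append((rec.patient_id, i, float(p), float(s)))
        return pd.DataFrame(
            rows, columns=["patient_id", "frame_index", "position", "true_severity"]
        )


def _stratified_positions(n: int, rng: np.random.Generator, jitter: bool) -> np.ndarray:
    """Strictly increasing positions in [0, 1]; one frame per stratum."""
    if jitter:
        return (np.arange(n) + rng.uniform(0.0, 1.0, size=n)) / n
    return (np.arange(n) + 0.5) / n


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a cohort; bitwise reproducible for a fixed master seed."""
    config.validate()
    master = np.random.default_rng(config.seed)
    patients = []
    for j in range(config.n_patients):
        params = ProfileParams(
            s0=float(master.uniform(*config.s0_range)),
            k=float(master.uniform(*config.k_range)),
            a=float(master.uniform(*config.a_range)),
            corr_length=float(master.uniform(*config.corr_length_range)),
        )
        profile_seed = int(master.integers(0, 2**31 - 1))
        profile = SeverityProfile(params, profile_seed, patient_id=f"pt{j:03d}")
        positions = _stratified_positions(config.frames_per_video, master, config.jitter)
        frame_seeds = master.integers(0, 2**31 - 1, size=config.frames_per_video)
        patients.append(
            PatientRecord(profile, positions, frame_seeds, config.image_size)
        )
    return Cohort(config=config, patients=patients)


def frame_content_seed(image: np.ndarray, salt: int = 0) -> int:
    """Deterministic per-frame seed derived from pixel content.

    Used by stochastic scorers so that scoring the same frame twice gives
    the same output while different frames (or orientations) draw
    independent noise.
    """
    h = zlib.crc32(np.ascontiguousarray(image).tobytes())
    return int((h ^ (salt & 0xFFFFFFFF)) % (2**31 - 1))
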