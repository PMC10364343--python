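"""Severity curves along the small intestine: net-error model, error-weighted
kernel fit, under-dispersion correction, and derived per-patient metrics.

Scored frames — whether from a dense machine read or a sparse 60-frame
expert read — are aggregated into a severity-versus-position curve by a
windowed inverse-variance weighted average: at each evaluation position
``p0`` the curve value is

    s(p0) = sum_i w_i s_i / sum_i w_i,   w_i = 1 / net_error(i, p0)^2

over the frames whose position lies within a window of total width 1/9 of
the SI centered on ``p0`` (half-width 1/18).  The *net error* of a frame,
relative to an evaluation position, combines independent error sources in
quadrature:

* frame prediction error — for machine reads, a linear blend of the
  network's predicted error and the dihedral orientation spread; for
  expert reads, the systematic individual-vs-consensus error (0.1875
  severity units, the mean absolute deviation of a single expert from the
  three-expert mean);
* distance decorrelation — severity decorrelates along the SI at an
  empirically measured 0.84 severity units per full SI length, so a frame
  a distance ``|p - p0|`` away contributes ``0.84 |p - p0|``;
* discretization — scores recorded on the integer 0-3 scale carry a
  rounding error whose RMS is ``sqrt(1/12) ~ 0.289`` (the RMS of a uniform
  error on [-1/2, 1/2]).

Curves are compared at the 10 evaluation points ``k/9, k = 0..9``: with a
window of total width 1/9, the windows of consecutive points touch but do
not overlap, so the 10 values are mutually independent.

Because inverse-variance averaging shrinks toward the window mean, fitted
machine curves can vary less across positions than the truth
(under-dispersion).  An optional one-sided correction re-inflates the
deviations from the patient's mean curve level by the factor
``sqrt(s_c^2 + mean(se^2)) / s_c`` (never deflating), where ``s_c`` is the
spread of the curve across the comparison points and ``se`` its effective
standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "NetErrorParams",
    "CurveFitParams",
    "SeverityCurve",
    "PatientMetrics",
    "net_error",
    "estimate_discretization_rmse",
    "fit_curve",
    "correct_underdispersion",
    "label_frames_from_curve",
    "comparison_points",
    "comparison_positions",
    "tertile_metrics",
    "first5_metric",
]

#: columns of a frame-observation table
OBS_COLUMNS = ["patient_id", "position", "score", "source", "pred_error", "orientation_spread"]


@dataclass(frozen=True)
class NetErrorParams:
    """Parameters of the multi-source net-error model.

    ``distance_coef`` is in severity units per full SI length;
    ``disc_rmse`` and ``sys_error`` in severity units.  ``frame_err_mix``
    is the weight of the network's predicted error in the blend with the
    orientation spread.  ``disc_for_mla`` keeps the discretization term for
    machine reads (the model was trained on discretized scores, so the
    rounding error retains a residual influence on its predictions).
    """

    distance_coef: float = 0.84
    disc_rmse: float = 0.289
    sys_error: float = 0.1875
    frame_err_mix: float = 0.5
    eps: float = 0.01
    disc_for_mla: bool = True

    def validate(self) -> None:
        if min(self.distance_coef, self.disc_rmse, self.sys_error, self.eps) < 0:
            raise ValueError("net-error components must be >= 0")
        if not 0.0 <= self.frame_err_mix <= 1.0:
            raise ValueError("frame_err_mix must be in [0, 1]")


@dataclass(frozen=True)
class CurveFitParams:
    """Window and grids of the curve fit.

    ``window`` is the *total* window width as a fraction of SI length
    (frames within ``window / 2`` of the evaluation point are used);
    ``n_dense`` the size of the dense plotting/metrics grid.  The
    comparison grid is always the 10 points ``k/9``.
    """

    window: float = 1.0 / 9.0
    n_dense: int = 200

    def validate(self) -> None:
        if not 0.0 < self.window <= 1.0:
            raise ValueError("window must be in (0, 1]")
        if self.n_dense < 2:
            raise ValueError("n_dense must be >= 2")


def comparison_positions() -> np.ndarray:
    """The 10 evenly distributed comparison points ``k/9, k = 0..9``."""
    return np.arange(10) / 9.0


@dataclass
class SeverityCurve:
    """A fitted severity curve for one patient and one source."""

    patient_id: str
    source: str
    grid: np.ndarray  # evaluation positions, sorted, includes k/9 points
    values: np.ndarray  # fitted severity, NaN where the window was empty
    stderr: np.ndarray  # effective standard error sqrt(1 / sum w)
    dispersion_factor: float = 1.0  # re-inflation factor applied (>= 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "source": self.source,
                "position": self.grid,
                "value": self.values,
                "stderr": self.stderr,
                "dispersion_factor": self.dispersion_factor,
            }
        )


@dataclass
class PatientMetrics:
    """Derived per-patient metrics (NaN where undefined)."""

    patient_id: str
    source: str
    first_tertile_mean: float
    first_tertile_max: float
    si_mean: float
    first5_mean: float = float("nan")


# --------------------------------------------------------------------------
# Net error
# --------------------------------------------------------------------------


def _frame_error_term(source, pred_error, orientation_spread, params: NetErrorParams):
    """Per-frame prediction-error component by source (vectorized)."""
    source = np.asarray(source)
    pred_error = np.asarray(pred_error, dtype=float)
    spread = np.asarray(orientation_spread, dtype=float)
    a = params.frame_err_mix
    out = np.where(
        source == "expert",
        params.sys_error,
        np.where(source == "truth", 0.0, a * pred_error + (1.0 - a) * spread),
    )
    return out


def net_error(
    position,
    eval_position,
    params: NetErrorParams | None = None,
    *,
    source="mla",
    pred_error=0.0,
    orientation_spread=0.0,
):
    """Net error of observation(s) relative to an evaluation position.

    Independent components — frame prediction error, distance
    decorrelation, discretization — are combined in quadrature and floored
    at ``params.eps``.
    """
    params = params or NetErrorParams()
    params.validate()
    frame_term = _frame_error_term(source, pred_error, orientation_spread, params)
    dist_term = params.distance_coef * np.abs(
        np.asarray(position, dtype=float) - float(eval_position)
    )
    src = np.asarray(source)
    disc_on = (src == "expert") | ((src == "mla") & params.disc_for_mla)
    disc_term = np.where(disc_on, params.disc_rmse, 0.0)
    total = np.sqrt(frame_term**2 + dist_term**2 + disc_term**2)
    out = np.maximum(total, params.eps)
    return float(out) if out.ndim == 0 else out


def estimate_discretization_rmse(n_draws: int = 1_000_000, seed: int = 0) -> float:
    """RMS rounding error of continuous [0, 3] severities forced onto the
    integer scale — bootstrap estimate of the analytic ``sqrt(1/12)``."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 3.0, size=n_draws)
    rounded = np.clip(np.rint(x), 0, 3)
    return float(np.sqrt(np.mean((x - rounded) ** 2)))


# --------------------------------------------------------------------------
# Curve fitting
# --------------------------------------------------------------------------


def _fit_grid(fit_params: CurveFitParams) -> np.ndarray:
    dense = np.linspace(0.0, 1.0, fit_params.n_dense)
    return np.union1d(np.round(dense, 12), np.round(comparison_positions(), 12))


def fit_curve(
    observations: pd.DataFrame,
    fit_params: CurveFitParams | None = None,
    err_params: NetErrorParams | None = None,
    grid: np.ndarray | None = None,
) -> SeverityCurve:
    """Windowed inverse-variance weighted fit of one patient+source table.

    ``observations`` needs columns ``position`` and ``score``; optional
    ``source`` (default ``mla``), ``pred_error``, ``orientation_spread``,
    ``patient_id``.  Grid points whose window holds no frame are NaN;
    raises ``ValueError`` if every window is empty.
    """
    fit_params = fit_params or CurveFitParams()
    err_params = err_params or NetErrorParams()
    fit_params.validate()
    err_params.validate()
    if len(observations) == 0:
        raise ValueError("no observations to fit")
    pos = observations["position"].to_numpy(dtype=float)
    score = observations["score"].to_numpy(dtype=float)
    source = (
        observations["source"].to_numpy()
        if "source" in observations
        else np.full(len(observations), "mla")
    )
    pred_error = (
        observations["pred_error"].to_numpy(dtype=float)
        if "pred_error" in observations
        else np.zeros(len(observations))
    )
    spread = (
        observations["orientation_spread"].to_numpy(dtype=float)
        if "orientation_spread" in observations
        else np.zeros(len(observations))
    )
    patient_id = (
        str(observations["patient_id"].iloc[0]) if "patient_id" in observations else "p0"
    )
    src_label = str(source[0]) if len(source) else "mla"

    if grid is None:
        grid = _fit_grid(fit_params)
    half = fit_params.window / 2.0
    values = np.full(grid.size, np.nan)
    stderr = np.full(grid.size, np.nan)
    for i, p0 in enumerate(grid):
        in_win = np.abs(pos - p0) <= half + 1e-12
        if not np.any(in_win):
            continue
        ne = net_error(
            pos[in_win],
            p0,
            err_params,
            source=source[in_win],
            pred_error=pred_error[in_win],
            orientation_spread=spread[in_win],
        )
        w = 1.0 / np.asarray(ne) ** 2
        values[i] = np.clip(np.sum(w * score[in_win]) / np.sum(w), 0.0, 3.0)
        stderr[i] = np.sqrt(1.0 / np.sum(w))
    if np.all(np.isnan(values)):
        raise ValueError("all windows empty; cannot fit a curve")
    return SeverityCurve(patient_id, src_label, grid, values, stderr)


def _comparison_mask(grid: np.ndarray) -> np.ndarray:
    cp = comparison_positions()
    return np.isclose(grid[:, None], cp[None, :], atol=1e-9).any(axis=1)


def comparison_points(curve: SeverityCurve) -> np.ndarray:
    """Curve values at the 10 comparison points ``k/9``.

    The default fit grid contains these positions exactly; for a custom
    grid the values are linearly interpolated.
    """
    cp = comparison_positions()
    mask = _comparison_mask(curve.grid)
    if mask.sum() == 10:
        return curve.values[mask]
    ok = ~np.isnan(curve.values)
    return np.interp(cp, curve.grid[ok], curve.values[ok])


def correct_underdispersion(curve: SeverityCurve) -> SeverityCurve:
    """One-sided variance re-inflation of a fitted curve.

    Let ``s_c`` be the spread of the curve over the comparison points and
    ``mse`` the mean squared effective standard error there.  If
    ``f = sqrt(s_c^2 + mse) / s_c > 1`` the deviations from the patient's
    mean curve level are multiplied by ``f`` (then re-clipped to [0, 3]);
    curves are never deflated.  The factor is recorded on the curve.
    """
    mask = _comparison_mask(curve.grid) & ~np.isnan(curve.values)
    vals = curve.values[mask]
    errs = curve.stderr[mask]
    if vals.size == 0:
        return replace(curve, dispersion_factor=1.0)
    s_c = float(np.std(vals))
    mse = float(np.mean(errs**2))
    if s_c <= 0 or mse <= 0:
        return replace(curve, dispersion_factor=1.0)
    f = float(np.sqrt(s_c**2 + mse) / s_c)
    if f <= 1.0:
        return replace(curve, dispersion_factor=1.0)
    mean = float(np.mean(vals))
    new_values = np.where(
        np.isnan(curve.values),
        np.nan,
        np.clip(mean + f * (curve.values - mean), 0.0, 3.0),
    )
    return replace(curve, values=new_values, dispersion_factor=f)


def label_frames_from_curve(curve: SeverityCurve, positions) -> np.ndarray:
    """Continuous training targets: curve values interpolated at ``positions``.

    Linear interpolation over the non-missing grid points; positions beyond
    the curve's ends clamp to the nearest end value.
    """
    ok = ~np.isnan(curve.values)
    if not np.any(ok):
        raise ValueError("curve has no fitted values")
    return np.interp(np.asarray(positions, dtype=float), curve.grid[ok], curve.values[ok])


# --------------------------------------------------------------------------
# Derived metrics
# --------------------------------------------------------------------------


def tertile_metrics(curve: SeverityCurve) -> PatientMetrics:
    """First-tertile mean/max and whole-SI mean of the dense curve."""
    ok = ~np.isnan(curve.values)
    first = ok & (curve.grid <= 1.0 / 3.0 + 1e-12)
    if np.any(first):
        ft_mean = float(np.mean(curve.values[first]))
        ft_max = float(np.max(curve.values[first]))
    else:
        ft_mean = ft_max = float("nan")
    si_mean = float(np.mean(curve.values[ok])) if np.any(ok) else float("nan")
    return PatientMetrics(curve.patient_id, curve.source, ft_mean, ft_max, si_mean)


def first5_metric(observations: pd.DataFrame) -> float:
    """Mean raw frame score in the first 5% of the SI; NaN if no frame there.

    Kept separate from the curve metrics: apparent proximal villous change
    immediately past the pylorus can reflect gastric injury rather than
    celiac enteropathy, so this region is sequestered into its own metric.
    """
    pos = observations["position"].to_numpy(dtype=float)
    mask = pos < 0.05
    if not np.any(mask):
        return float("nan")
    return float(observations["score"].to_numpy(dtype=float)[mask].mean())
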