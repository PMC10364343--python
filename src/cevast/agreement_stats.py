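"""Inter-rater agreement statistics: Krippendorff's alpha and R².

Krippendorff's alpha is a chance-corrected reliability coefficient,
``alpha = 1 - D_o / D_e``: the ratio of observed to expected disagreement,
computed over all pairable values so that any number of raters and
arbitrary missingness are handled.  For interval data the disagreement
metric is the squared difference ``(v - v')^2``.  Alpha is 1 for perfect
agreement, 0 at chance level, and can go negative for systematic
disagreement.

Interpretation follows the conventional kappa-like bins: below 0.1 no
agreement, 0.2-0.4 fair, 0.4-0.6 moderate, 0.6-0.8 substantial, above 0.8
almost perfect.  The conventional bin list leaves 0.1-0.2 unlabeled; this
module labels it "slight agreement" so every value gets a bin.  Bins are
half-open ``[lo, hi)`` with the top bin closed at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AgreementResult",
    "krippendorff_alpha",
    "interpret_alpha",
    "r_squared",
    "agreement_report",
]


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given data."""


@dataclass
class AgreementResult:
    comparison: str
    statistic: str  # "alpha" or "r_squared"
    value: float
    n_items: int
    interpretation: str


def krippendorff_alpha(ratings, metric: str = "interval") -> float:
    """Krippendorff's alpha from a raters × items matrix (NaN = missing).

    Coincidence-matrix formulation: items with fewer than two ratings are
    dropped; within each remaining item every ordered pair of values
    contributes ``1 / (m_u - 1)`` to the coincidence count.  With interval
    metric ``delta(c, k) = (c - k)^2``.  If the expected disagreement is
    zero (all pairable values identical) alpha is 1 by convention.
    """
    if metric != "interval":
        raise NotImplementedError("only the interval metric is implemented")
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2:
        raise ValueError("ratings must be a 2-D matrix with >= 2 raters")
    counts = np.sum(~np.isnan(R), axis=0)
    keep = counts >= 2
    if not np.any(keep):
        raise UndefinedStatisticError("no item carries two or more ratings")
    R = R[:, keep]
    m_u = counts[keep]

    vals = R[~np.isnan(R)]
    uniq, inv = np.unique(vals, return_inverse=True)
    V = uniq.size
    # per-unit value counts n_uc
    n_uc = np.zeros((R.shape[1], V))
    col_idx = np.where(~np.isnan(R))[1]
    np.add.at(n_uc, (col_idx, inv), 1.0)
    # coincidence matrix o_ck = sum_u n_uc (n_uk - delta_ck) / (m_u - 1)
    scale = 1.0 / (m_u - 1.0)
    O = (n_uc * scale[:, None]).T @ n_uc
    O[np.diag_indices(V)] -= (n_uc * scale[:, None]).sum(axis=0)
    n_c = O.sum(axis=1)
    n_tot = n_c.sum()
    delta = (uniq[:, None] - uniq[None, :]) ** 2
    d_o = np.sum(O * delta) / n_tot
    d_e = np.sum(np.outer(n_c, n_c) * delta) / (n_tot * (n_tot - 1.0))
    if d_e == 0.0:
        return 1.0  # no expected disagreement: perfect by convention
    return float(1.0 - d_o / d_e)


_BINS = [
    (0.1, "no agreement"),
    (0.2, "slight agreement"),  # fills the conventional gap between 0.1 and 0.2
    (0.4, "fair agreement"),
    (0.6, "moderate agreement"),
    (0.8, "substantial agreement"),
]


def interpret_alpha(alpha: float) -> str:
    """Qualitative bin for an alpha value (half-open bins, top bin >= 0.8)."""
    if alpha > 1.0:
        raise ValueError("alpha cannot exceed 1")
    for hi, label in _BINS:
        if alpha < hi:
            return label
    return "almost perfect agreement"


def r_squared(x, y) -> float:
    """Squared Pearson correlation of paired values; NaN pairs dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise UndefinedStatisticError("need at least 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("zero variance; R^2 undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


# --------------------------------------------------------------------------
# Study-level report
# --------------------------------------------------------------------------


def _pivot(values: pd.DataFrame) -> np.ndarray:
    """Tidy (rater, item, value) table -> raters × items matrix."""
    wide = values.pivot_table(index="rater", columns="item", values="value", aggfunc="mean")
    return wide.to_numpy()


def agreement_report(
    reader_points: pd.DataFrame,
    mla_points: pd.DataFrame,
    reader_metrics: pd.DataFrame,
    mla_metrics: pd.DataFrame,
) -> pd.DataFrame:
    """The headline agreement comparisons of a whole study.

    Inputs are tidy tables.  ``reader_points``: columns
    ``rater, item, value`` with one item per (patient, comparison point)
    and one rater per expert.  ``mla_points``: columns ``item, value`` on
    the same items.  ``reader_metrics`` / ``mla_metrics``: columns
    ``patient_id, metric, value`` (reader metrics averaged over the panel).

    Returns a tidy results table with Krippendorff's alpha for (i) the
    expert panel's curve values, (ii) mean-reader vs machine curve values,
    (iii) each derived metric, plus R² for mean-reader vs machine metrics.
    """
    if not set(mla_points["item"]) & set(reader_points["item"]):
        raise ValueError("no overlapping items between readers and machine read")
    rows: list[AgreementResult] = []

    mat = _pivot(reader_points)
    a = krippendorff_alpha(mat)
    rows.append(AgreementResult("inter_reader_curves", "alpha", a, mat.shape[1], interpret_alpha(a)))

    mean_reader = reader_points.groupby("item", sort=True)["value"].mean()
    mla = mla_points.set_index("item")["value"]
    items = mean_reader.index.intersection(mla.index)
    mat2 = np.vstack([mean_reader.loc[items].to_numpy(), mla.loc[items].to_numpy()])
    a = krippendorff_alpha(mat2)
    rows.append(
        AgreementResult("mean_reader_vs_mla_curves", "alpha", a, len(items), interpret_alpha(a))
    )

    rm = reader_metrics.pivot_table(index="patient_id", columns="metric", values="value")
    mm = mla_metrics.pivot_table(index="patient_id", columns="metric", values="value")
    patients = rm.index.intersection(mm.index)
    if len(patients) == 0:
        raise ValueError("no overlapping patients between metric tables")
    for metric in ["first_tertile_mean", "first_tertile_max", "si_mean"]:
        x = rm.loc[patients, metric].to_numpy()
        y = mm.loc[patients, metric].to_numpy()
        a = krippendorff_alpha(np.vstack([x, y]))
        rows.append(AgreementResult(f"{metric}", "alpha", a, len(patients), interpret_alpha(a)))
        rows.append(AgreementResult(f"{metric}", "r_squared", r_squared(x, y), len(patients), ""))

    return pd.DataFrame([r.__dict__ for r in rows])
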