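"""End-to-end synthetic study: cohort → scoring → curves → agreement.

Mirrors the full reading workflow: a cohort of patients with latent
severity profiles is read densely by the machine scorer (every frame, in
all eight orientations, ensembled) and sparsely by a panel of simulated
expert readers (60 discretized scores per video); severity curves are
fitted per patient and per rater with the net-error-weighted kernel fit;
derived metrics and the headline agreement statistics are computed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .agreement_stats import agreement_report
from .curve_model import (
    CurveFitParams,
    NetErrorParams,
    SeverityCurve,
    comparison_points,
    comparison_positions,
    correct_underdispersion,
    first5_metric,
    fit_curve,
    tertile_metrics,
)
from .ensemble import score_frame_ensembled
from .reader_sim import ReaderModel, calibrate_reader_noise, simulate_reader_scores
from .scorer import OracleScorer
from .synthetic_data import Cohort, CohortConfig, generate_cohort

logger = logging.getLogger("cevast")

__all__ = ["StudyConfig", "StudyResult", "run_study", "score_cohort", "simulate_expert_reads"]


@dataclass
class StudyConfig:
    """Configuration of a complete synthetic study.

    Defaults describe the reference desk-scale study: 20 patients, a dense
    machine read of 2000 frames per video, a panel of 3 experts scoring 60
    frames per video, machine read noise of 0.3 severity units per
    orientation, and reader noise calibrated so that an individual
    expert's MAE against the 3-expert mean is 0.1875.
    """

    n_patients: int = 20
    mla_frames: int = 2000
    expert_frames: int = 60
    n_readers: int = 3
    image_size: int = 64
    seed: int = 0
    oracle_noise_sd: float = 0.3
    reader_noise_sd: float | None = None  # None => calibrate to target_reader_mae
    target_reader_mae: float = 0.1875
    dispersion_correction: bool = True
    net_error: NetErrorParams = field(default_factory=NetErrorParams)
    curve_fit: CurveFitParams = field(default_factory=CurveFitParams)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data)
        if "seed" not in data:
            raise ValueError("config must carry an explicit seed")
        if "net_error" in data and isinstance(data["net_error"], dict):
            data["net_error"] = NetErrorParams(**data["net_error"])
        if "curve_fit" in data and isinstance(data["curve_fit"], dict):
            data["curve_fit"] = CurveFitParams(**data["curve_fit"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class StudyResult:
    config: StudyConfig
    reader_noise_sd: float
    observations: pd.DataFrame  # all frame observations (mla + expert)
    curves: pd.DataFrame  # long table of fitted curves
    metrics: pd.DataFrame  # per patient × source derived metrics
    agreement: pd.DataFrame  # headline statistics
    truth: pd.DataFrame  # ground-truth frame table


def score_cohort(cohort: Cohort, model, ensemble: bool = True) -> pd.DataFrame:
    """Machine-read every frame of the cohort; returns an observation table."""
    rows = []
    for rec in cohort.patients:
        t0 = time.perf_counter()
        for fr in rec.iter_frames():
            fs = score_frame_ensembled(model, fr) if ensemble else model.score_frame(fr)
            rows.append(
                (
                    rec.patient_id,
                    fr.frame_index,
                    fr.position,
                    fs.severity,
                    "mla",
                    "mla",
                    fs.error,
                    fs.orientation_spread if fs.orientation_spread is not None else 0.0,
                )
            )
        logger.info(
            "scored %s: %d frames in %.1fs",
            rec.patient_id,
            len(rec.positions),
            time.perf_counter() - t0,
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "frame_index",
            "position",
            "score",
            "source",
            "reader_id",
            "pred_error",
            "orientation_spread",
        ],
    )


def simulate_expert_reads(
    cohort: Cohort,
    readers: list[ReaderModel],
    frames_per_video: int,
    seed: int,
) -> pd.DataFrame:
    """Panel of simulated experts scoring a sparse stratified frame sample."""
    rng = np.random.default_rng(seed)
    rows = []
    for rec in cohort.patients:
        n = frames_per_video
        positions = (np.arange(n) + rng.uniform(0.0, 1.0, size=n)) / n
        for reader in readers:
            r_seed = int(
                np.random.default_rng([reader.seed, rec.profile.seed]).integers(0, 2**31 - 1)
            )
            scores = simulate_reader_scores(
                rec.profile, positions, ReaderModel(reader.reader_id, reader.bias, reader.noise_sd, r_seed)
            )
            for i, (p, s) in enumerate(zip(positions, scores)):
                rows.append(
                    (rec.patient_id, i, float(p), float(s), "expert", reader.reader_id, 0.0, 0.0)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "frame_index",
            "position",
            "score",
            "source",
            "reader_id",
            "pred_error",
            "orientation_spread",
        ],
    )


def _mean_curve(curves: list[SeverityCurve], patient_id: str, source: str) -> SeverityCurve:
    """Pointwise mean of curves sharing a grid (the panel-average curve)."""
    grid = curves[0].grid
    vals = np.nanmean(np.vstack([c.values for c in curves]), axis=0)
    errs = np.sqrt(np.nanmean(np.vstack([c.stderr**2 for c in curves]), axis=0) / len(curves))
    return SeverityCurve(patient_id, source, grid, vals, errs)


def run_study(config: StudyConfig | None = None) -> StudyResult:
    """Run the complete synthetic study and compute agreement statistics."""
    config = config or StudyConfig()
    seeds = np.random.default_rng(config.seed)
    s_cohort, s_readers, s_positions, s_model = (
        int(seeds.integers(0, 2**31 - 1)) for _ in range(4)
    )
    logger.info(
        "study seeds: cohort=%d readers=%d positions=%d model=%d",
        s_cohort, s_readers, s_positions, s_model,
    )

    cohort = generate_cohort(
        CohortConfig(
            n_patients=config.n_patients,
            frames_per_video=config.mla_frames,
            image_size=config.image_size,
            seed=s_cohort,
        )
    )

    noise_sd = (
        config.reader_noise_sd
        if config.reader_noise_sd is not None
        else calibrate_reader_noise(config.target_reader_mae, seed=s_readers)
    )
    logger.info("reader noise sd: %.4f", noise_sd)
    readers = [
        ReaderModel(f"reader{r + 1}", 0.0, noise_sd, seed=s_readers + r)
        for r in range(config.n_readers)
    ]

    model = OracleScorer(noise_sd=config.oracle_noise_sd, seed=s_model)
    mla_obs = score_cohort(cohort, model)
    expert_obs = simulate_expert_reads(cohort, readers, config.expert_frames, s_positions)
    observations = pd.concat([mla_obs, expert_obs], ignore_index=True)

    # ---- curves -------------------------------------------------------
    curve_rows, metric_rows = [], []
    reader_point_rows, mla_point_rows = [], []
    cp = comparison_positions()
    for rec in cohort.patients:
        pid = rec.patient_id
        mla_df = mla_obs[mla_obs.patient_id == pid]
        curve = fit_curve(mla_df, config.curve_fit, config.net_error)
        if config.dispersion_correction:
            curve = correct_underdispersion(curve)
        curve_rows.append(curve.to_frame().assign(rater="mla"))
        pts = comparison_points(curve)
        mla_point_rows += [
            {"item": f"{pid}:{k}", "value": v} for k, v in zip(range(10), pts)
        ]
        m = tertile_metrics(curve)
        metric_rows.append(
            {
                "patient_id": pid,
                "source": "mla",
                "first_tertile_mean": m.first_tertile_mean,
                "first_tertile_max": m.first_tertile_max,
                "si_mean": m.si_mean,
                "first5_mean": first5_metric(mla_df),
            }
        )

        reader_curves = []
        for reader in readers:
            rdf = expert_obs[(expert_obs.patient_id == pid) & (expert_obs.reader_id == reader.reader_id)]
            rc = fit_curve(rdf, config.curve_fit, config.net_error)
            reader_curves.append(rc)
            curve_rows.append(rc.to_frame().assign(rater=reader.reader_id))
            for k, v in zip(range(10), comparison_points(rc)):
                reader_point_rows.append(
                    {"rater": reader.reader_id, "item": f"{pid}:{k}", "value": v}
                )
        mean_curve = _mean_curve(reader_curves, pid, "expert")
        curve_rows.append(mean_curve.to_frame().assign(rater="mean_reader"))
        m = tertile_metrics(mean_curve)
        expert_pid = expert_obs[expert_obs.patient_id == pid]
        metric_rows.append(
            {
                "patient_id": pid,
                "source": "expert",
                "first_tertile_mean": m.first_tertile_mean,
                "first_tertile_max": m.first_tertile_max,
                "si_mean": m.si_mean,
                "first5_mean": first5_metric(expert_pid),
            }
        )

    curves = pd.concat(curve_rows, ignore_index=True)
    metrics = pd.DataFrame(metric_rows)

    # ---- agreement ----------------------------------------------------
    tidy_metrics = metrics.melt(
        id_vars=["patient_id", "source"],
        value_vars=["first_tertile_mean", "first_tertile_max", "si_mean"],
        var_name="metric",
        value_name="value",
    )
    agreement = agreement_report(
        pd.DataFrame(reader_point_rows),
        pd.DataFrame(mla_point_rows),
        tidy_metrics[tidy_metrics.source == "expert"],
        tidy_metrics[tidy_metrics.source == "mla"],
    )

    return StudyResult(
        config=config,
        reader_noise_sd=noise_sd,
        observations=observations,
        curves=curves,
        metrics=metrics,
        agreement=agreement,
        truth=cohort.truth_table(),
    )
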