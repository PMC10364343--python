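"""Versioned CSV schemas and frame export/import.

Every table written by the package carries a ``schema_version`` column
("major.minor"); readers reject files whose major version they do not
understand, so stale outputs from incompatible versions fail loudly rather
than silently mis-parsing.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1.0"

#: column contracts, by table kind
SCHEMAS = {
    "manifest": ["patient_id", "frame_index", "position", "path"],
    "truth": ["patient_id", "frame_index", "position", "true_severity"],
    "frame_scores": [
        "patient_id",
        "frame_index",
        "position",
        "score",
        "source",
        "reader_id",
        "pred_error",
        "orientation_spread",
    ],
    "curves": ["patient_id", "source", "rater", "position", "value", "stderr", "dispersion_factor"],
    "metrics": [
        "patient_id",
        "source",
        "first_tertile_mean",
        "first_tertile_max",
        "si_mean",
        "first5_mean",
    ],
    "agreement": ["comparison", "statistic", "value", "n_items", "interpretation"],
}


class SchemaError(ValueError):
    """Raised for unknown schema kinds or incompatible versions."""


def write_table(df: pd.DataFrame, path, kind: str) -> None:
    """Write a table with its schema-version column; columns are validated."""
    if kind not in SCHEMAS:
        raise SchemaError(f"unknown table kind {kind!r}")
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table missing columns: {missing}")
    out = df.copy()
    out["schema_version"] = SCHEMA_VERSION
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def read_table(path, kind: str) -> pd.DataFrame:
    """Read and validate a versioned table; rejects unknown major versions."""
    if kind not in SCHEMAS:
        raise SchemaError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path)
    if "schema_version" in df.columns and len(df):
        major = str(df["schema_version"].iloc[0]).split(".")[0]
        if major != SCHEMA_VERSION.split(".")[0]:
            raise SchemaError(
                f"{path}: schema major version {major} not supported "
                f"(expected {SCHEMA_VERSION.split('.')[0]})"
            )
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: {kind} table missing columns: {missing}")
    return df.drop(columns=["schema_version"], errors="ignore")


def export_cohort(cohort, out_dir, write_truth: bool = True) -> pd.DataFrame:
    """Write cohort frames as PNG plus manifest (and truth) CSVs.

    Returns the manifest.  Frame files land under
    ``<out_dir>/frames/<patient_id>/frame_<index>.png``.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    rows = []
    for rec in cohort.patients:
        pdir = out_dir / "frames" / rec.patient_id
        pdir.mkdir(parents=True, exist_ok=True)
        for fr in rec.iter_frames():
            rel = os.path.join("frames", rec.patient_id, f"frame_{fr.frame_index:05d}.png")
            iio.imwrite(out_dir / rel, fr.image)
            rows.append(
                (rec.patient_id, fr.frame_index, fr.position, rel, fr.true_severity)
            )
    manifest = pd.DataFrame(
        rows, columns=["patient_id", "frame_index", "position", "path", "true_severity"]
    )
    write_table(manifest, out_dir / "manifest.csv", "manifest")
    if write_truth:
        write_table(cohort.truth_table(), out_dir / "truth.csv", "truth")
    return manifest


def load_frames(manifest: pd.DataFrame, root) -> "list":
    """Load manifest frames as arrays (order of the manifest)."""
    import imageio.v3 as iio

    root = Path(root)
    return [iio.imread(root / p) for p in manifest["path"]]
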