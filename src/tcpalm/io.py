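"""File formats and run configuration.

Localization tables travel as CSV with the columns
``frame, t_s, x_nm, y_nm, photons, sigma_nm`` (frame, x_nm, y_nm
required; the rest optional — ``t_s`` is synthesised from the frame
index when absent).  Detection-count profiles (one trace per cluster,
as published in source-data tables) load from wide or long CSV; image
stacks are multi-frame grayscale TIFF; configuration is YAML; fit
reports are JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .photophysics import ClusterScenario, CumulantTrace, PhotophysicsParams

__all__ = [
    "read_localizations",
    "write_localizations",
    "ProfileTable",
    "read_profile_table",
    "read_image_stack",
    "write_image_stack",
    "load_config",
    "save_report",
    "RunConfig",
    "run_stage",
]

logger = logging.getLogger("tcpalm")

REQUIRED_COLUMNS = ("frame", "x_nm", "y_nm")
OPTIONAL_COLUMNS = ("t_s", "photons", "sigma_nm")


def read_localizations(path, frame_time: float = 0.06) -> pd.DataFrame:
    """Load and validate a localization table.

    Missing required columns and non-numeric cells are rejected with
    the offending column name / row index; unknown extra columns are
    preserved and ignored by analysis.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column: {col}")
    for col in REQUIRED_COLUMNS + tuple(c for c in OPTIONAL_COLUMNS if c in df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric value in column {col!r} at row {int(bad.idxmax())}"
            )
        if coerced.isna().any():
            raise ValueError(f"missing value in column {col!r}")
        df[col] = coerced
    if (df["frame"] < 0).any():
        raise ValueError("negative frame index")
    df["frame"] = df["frame"].astype(int)
    if "t_s" not in df.columns:
        df["t_s"] = df["frame"] * frame_time
    return df


def write_localizations(series: pd.DataFrame, path) -> None:
    cols = [c for c in ("frame", "t_s", "x_nm", "y_nm", "photons", "sigma_nm") if c in series.columns]
    series.to_csv(path, index=False, columns=cols)


@dataclass
class ProfileTable:
    """Loaded source-data table: per-cluster traces or a scalar series."""

    kind: str  # "traces" | "scalars"
    traces: list = field(default_factory=list)
    values: np.ndarray | None = None
    labels: list = field(default_factory=list)
    source: str = ""


def read_profile_table(path, frame_time: float = 0.06) -> ProfileTable:
    """Load per-frame detection profiles or a scalar (lifetime) list.

    Accepted layouts: long format with columns ``cluster_id, frame,
    count``; wide format with one column per cluster (rows = frames);
    a single column of scalars (lifetime lists and the like) loads in
    scalar mode.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValueError(f"empty profile table: {path}")
    if df.isna().any().any():
        raise ValueError("ragged or missing cells in profile table")
    cols = [c.lower() for c in df.columns]
    if {"cluster_id", "frame", "count"} <= set(cols):
        df.columns = cols
        traces, labels = [], []
        for cid, grp in df.groupby("cluster_id"):
            n_frames = int(grp["frame"].max()) + 1
            counts = np.zeros(n_frames, dtype=np.int64)
            counts[grp["frame"].astype(int)] = grp["count"].astype(int)
            traces.append(CumulantTrace(counts=counts, frame_time=frame_time, label=str(cid)))
            labels.append(str(cid))
        return ProfileTable("traces", traces=traces, labels=labels, source=str(path))
    if df.shape[1] == 1:
        vals = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy(dtype=float)
        return ProfileTable(
            "scalars", values=vals, labels=[str(df.columns[0])], source=str(path)
        )
    traces, labels = [], []
    for col in df.columns:
        counts = pd.to_numeric(df[col], errors="raise").to_numpy()
        traces.append(
            CumulantTrace(counts=counts.astype(np.int64), frame_time=frame_time, label=str(col))
        )
        labels.append(str(col))
    return ProfileTable("traces", traces=traces, labels=labels, source=str(path))


def read_image_stack(path) -> np.ndarray:
    return tifffile.imread(path)


def write_image_stack(stack: np.ndarray, path) -> None:
    """Write a stack as 16-bit multi-frame grayscale TIFF."""
    arr = np.clip(np.asarray(stack), 0, 2**16 - 1).astype(np.uint16)
    tifffile.imwrite(path, arr)


# ---------------------------------------------------------------------------
# Configuration and staged runs
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def photophysics_from_config(cfg: dict) -> PhotophysicsParams:
    return PhotophysicsParams(**cfg.get("photophysics", {}))


def scenario_from_config(cfg: dict) -> ClusterScenario:
    return ClusterScenario(**cfg.get("scenario", {}))


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)


@dataclass
class RunConfig:
    """One reproducible stage invocation."""

    stage: str
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."

    def config_hash(self) -> str:
        blob = json.dumps(
            {"stage": self.stage, "inputs": self.inputs, "params": self.params, "seed": self.seed},
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_stage(config: RunConfig) -> dict:
    """Dispatch a named analysis stage; returns paths of written artifacts.

    Stages mirror the CLI subcommands; identical config + seed produce
    byte-identical outputs.  The log records the stage, config hash and
    seed for provenance.
    """
    from . import stages  # local import to avoid cycles

    runner = stages.STAGES.get(config.stage)
    if runner is None:
        raise ValueError(
            f"unknown stage {config.stage!r}; available: {sorted(stages.STAGES)}"
        )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info(
        "stage=%s hash=%s seed=%d out=%s",
        config.stage,
        config.config_hash(),
        config.seed,
        out_dir,
    )
    artifacts = runner(config, out_dir)
    logger.info("stage=%s done: %s", config.stage, sorted(artifacts))
    return artifacts
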