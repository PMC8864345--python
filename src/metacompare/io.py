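"""CSV readers/writers, configuration and logging helpers.

The interchange schema for study-level data is one row per study:

    phenomenon_id, study_label, estimate, variance | standard_error
    [, direction_flip]

Exactly one of ``variance`` / ``standard_error`` is required; when both
are present they must agree (variance == standard_error**2 within 1e-6).
``direction_flip`` (optional boolean) negates the estimate so that the
hypothesized direction is positive.  External datasets with different
column names are adapted through a mapping (dict or YAML file of
``external_name: schema_name`` entries) rather than hard-coded logic.

MLR summary tables carry one row per phenomenon:

    phenomenon_id, mlr_estimate, mlr_variance | mlr_standard_error
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compare import AnalysisConfig
from .data import MetaDataset, PhenomenonPair, StudyRecord

__all__ = [
    "read_study_table",
    "write_study_table",
    "read_mlr_table",
    "write_mlr_table",
    "read_pairs",
    "write_pairs",
    "load_config",
    "load_column_mapping",
    "get_logger",
]

logger = logging.getLogger("metacompare")


def get_logger(verbose: bool = False) -> logging.Logger:
    """Package logger writing to stderr."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
    return logger


def load_column_mapping(path: str | Path) -> dict[str, str]:
    """Read an ``external_name: schema_name`` YAML mapping."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise ValueError(f"column mapping {path} must be a flat YAML mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def _resolve_variance(df: pd.DataFrame, var_col: str, se_col: str) -> pd.Series:
    has_var = var_col in df.columns
    has_se = se_col in df.columns
    if not has_var and not has_se:
        raise ValueError(f"need a {var_col!r} or {se_col!r} column")
    if has_var and has_se:
        mismatch = ~np.isclose(
            df[var_col].to_numpy(float),
            df[se_col].to_numpy(float) ** 2,
            atol=1e-6,
            rtol=0,
        )
        if mismatch.any():
            bad = df.index[mismatch].tolist()
            raise ValueError(
                f"variance and {se_col}**2 disagree beyond 1e-6 in rows {bad}"
            )
        return df[var_col].astype(float)
    if has_var:
        return df[var_col].astype(float)
    return df[se_col].astype(float) ** 2


def read_study_table(
    path: str | Path,
    column_mapping: dict[str, str] | str | Path | None = None,
) -> list[MetaDataset]:
    """Read a study-level CSV into one :class:`MetaDataset` per phenomenon.

    Rows are grouped by ``phenomenon_id`` (order of first appearance);
    ``direction_flip`` rows are negated; invariants (finite estimates,
    positive variances, unique labels) are validated with the offending
    study label in any error message.
    """
    df = pd.read_csv(path)
    if isinstance(column_mapping, (str, Path)):
        column_mapping = load_column_mapping(column_mapping)
    if column_mapping:
        df = df.rename(columns=column_mapping)

    for col in ("phenomenon_id", "study_label", "estimate"):
        if col not in df.columns:
            raise ValueError(f"study table is missing required column {col!r}")
    variance = _resolve_variance(df, "variance", "standard_error")
    df = df.assign(variance=variance)

    estimates = df["estimate"].to_numpy(float)
    if "direction_flip" in df.columns:
        flip = df["direction_flip"].fillna(False).astype(bool).to_numpy()
        estimates = np.where(flip, -estimates, estimates)

    datasets: list[MetaDataset] = []
    for pid in df["phenomenon_id"].astype(str).drop_duplicates():
        mask = (df["phenomenon_id"].astype(str) == pid).to_numpy()
        studies = []
        for label, y, v in zip(
            df.loc[mask, "study_label"].astype(str),
            estimates[mask],
            df.loc[mask, "variance"],
        ):
            try:
                studies.append(StudyRecord(float(y), float(v), label))
            except ValueError as exc:
                raise ValueError(f"phenomenon {pid!r}: {exc}") from exc
        datasets.append(MetaDataset(studies=tuple(studies), phenomenon_id=pid))
        logger.debug("phenomenon %s: %d studies", pid, len(studies))
    return datasets


def write_study_table(datasets: list[MetaDataset], path: str | Path) -> None:
    pd.concat([d.to_frame() for d in datasets], ignore_index=True).to_csv(
        path, index=False
    )


def read_mlr_table(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read one MLR summary per phenomenon as ``{id: (estimate, variance)}``."""
    df = pd.read_csv(path)
    for col in ("phenomenon_id", "mlr_estimate"):
        if col not in df.columns:
            raise ValueError(f"MLR table is missing required column {col!r}")
    variance = _resolve_variance(df, "mlr_variance", "mlr_standard_error")
    return {
        str(pid): (float(est), float(var))
        for pid, est, var in zip(df["phenomenon_id"], df["mlr_estimate"], variance)
    }


def write_mlr_table(pairs: list[PhenomenonPair], path: str | Path) -> None:
    pd.DataFrame(
        {
            "phenomenon_id": [p.phenomenon_id for p in pairs],
            "mlr_estimate": [p.mlr_estimate for p in pairs],
            "mlr_variance": [p.mlr_variance for p in pairs],
        }
    ).to_csv(path, index=False)


def read_pairs(
    study_path: str | Path,
    mlr_path: str | Path,
    column_mapping: dict[str, str] | str | Path | None = None,
) -> list[PhenomenonPair]:
    """Join a study table and an MLR table into phenomenon pairs."""
    datasets = read_study_table(study_path, column_mapping=column_mapping)
    mlr = read_mlr_table(mlr_path)
    pairs = []
    for ds in datasets:
        if ds.phenomenon_id not in mlr:
            raise ValueError(
                f"phenomenon {ds.phenomenon_id!r} has no MLR summary row"
            )
        est, var = mlr[ds.phenomenon_id]
        pairs.append(
            PhenomenonPair(
                meta=ds,
                mlr_estimate=est,
                mlr_variance=var,
                phenomenon_id=ds.phenomenon_id,
            )
        )
    return pairs


def write_pairs(
    pairs: list[PhenomenonPair], study_path: str | Path, mlr_path: str | Path
) -> None:
    write_study_table([p.meta for p in pairs], study_path)
    write_mlr_table(pairs, mlr_path)


def load_config(path: str | Path) -> AnalysisConfig:
    """Read the pipeline configuration from a flat YAML file.

    Recognized keys: tau2_method, interval_method, alpha, n_boot, seed,
    eta_list.  Missing keys fall back to the defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat YAML mapping")
    known = {
        "tau2_method",
        "interval_method",
        "alpha",
        "n_boot",
        "seed",
        "eta_list",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "eta_list" in raw:
        raw["eta_list"] = tuple(float(e) for e in raw["eta_list"])
    return AnalysisConfig(**raw)
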