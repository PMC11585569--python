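"""Readers and writers for the package's plain-text formats.

Covariance, fluctuation, sign and bound matrices travel as labelled square
CSVs (first row and first column are species identifiers, comma separator,
'.' decimal, UTF-8).  Writers use ``repr``-precision floats so a
write -> read round trip is exact and repeated runs with the same seed are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_labeled_matrix",
    "write_labeled_matrix",
    "read_fluctuation_structure",
    "write_fluctuation_structure",
    "sample_covariance",
    "load_yaml_config",
    "require_keys",
    "write_json",
]


def read_labeled_matrix(path) -> pd.DataFrame:
    """Labelled square matrix from CSV; validates labels and numeric cells."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, expected square"
        )
    if list(df.index) != list(df.columns):
        rows_only = [x for x in df.index if x not in set(df.columns)]
        cols_only = [x for x in df.columns if x not in set(df.index)]
        raise ValueError(
            f"{path}: row/column labels differ (rows only: {rows_only}, "
            f"columns only: {cols_only}, or ordering mismatch)"
        )
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    return df


def write_labeled_matrix(matrix, labels, path) -> None:
    """Write a labelled square matrix as CSV with full float precision."""
    M = np.asarray(matrix, dtype=float)
    labels = list(labels)
    if M.shape != (len(labels), len(labels)):
        raise ValueError("matrix shape does not match label count")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("," + ",".join(labels) + "\n")
        for lab, row in zip(labels, M):
            fh.write(lab + "," + ",".join(repr(float(x)) for x in row) + "\n")


def read_fluctuation_structure(sign_path, bounds_path=None, diag_scale=1.0):
    """Fluctuation structure from labelled CSVs (sign matrix, optional
    bounds matrix with matching labels).  Returns (structure, labels)."""
    from .fluctuation import FluctuationStructure

    sign_df = read_labeled_matrix(sign_path)
    labels = list(sign_df.index)
    bounds = None
    if bounds_path is not None:
        bdf = read_labeled_matrix(bounds_path)
        if list(bdf.index) != labels:
            raise ValueError("bounds labels do not match sign labels")
        bounds = bdf.to_numpy()
    structure = FluctuationStructure(
        sign_df.to_numpy().astype(int), bounds=bounds, diag_scale=diag_scale
    )
    return structure, labels


def write_fluctuation_structure(structure, labels, sign_path, bounds_path=None):
    write_labeled_matrix(structure.sign, labels, sign_path)
    if bounds_path is not None:
        if structure.bounds is None:
            raise ValueError("structure has no bounds to write")
        write_labeled_matrix(structure.bounds, labels, bounds_path)


def sample_covariance(samples: pd.DataFrame) -> pd.DataFrame:
    """Convenience: metabolite covariance from a metabolites x samples table."""
    return samples.T.cov()


def load_yaml_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def require_keys(cfg: dict, allowed: set[str], required: set[str], where: str) -> None:
    """Schema check: reject unknown keys, demand required ones."""
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"{where}: unknown config keys {sorted(unknown)}")
    missing = required - set(cfg)
    if missing:
        raise ValueError(f"{where}: missing config keys {sorted(missing)}")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
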