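"""File formats: tidy phenotype CSV, labelled square matrices, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_phenotypes", "write_phenotypes", "read_square_matrix",
           "write_square_matrix", "write_fit_report", "write_json"]

PHENOTYPE_COLUMNS = ["cycle", "stage", "year", "location", "trial", "rep",
                     "block", "tester", "entry", "yield"]


def read_phenotypes(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a tidy plot-level phenotype table; optional column renaming."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    if "is_check" not in df.columns:
        df["is_check"] = False
    df["entry"] = df["entry"].astype(str)
    return df


def write_phenotypes(plots: pd.DataFrame, path) -> None:
    plots.to_csv(path, index=False)


def read_square_matrix(path) -> pd.DataFrame:
    """Labelled square CSV (entry labels as header and first column)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels disagree")
    return df


def write_square_matrix(df: pd.DataFrame, path) -> None:
    if list(df.index) != list(df.columns):
        raise ValueError("square matrix labels disagree")
    df.to_csv(path, index_label="entry")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, tuple)):
        return sorted(map(str, obj)) if isinstance(obj, set) else list(obj)
    return str(obj)


def write_json(payload: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)


def write_fit_report(results, path, extra: dict | None = None) -> None:
    """Serialize a mixed-model fit: components, SEs, logREML, convergence."""
    comp = results.components().reset_index().rename(columns={"index": "component"})
    payload = {
        "log_reml_likelihood": results.llf,
        "converged": results.converged,
        "n_iterations": results.n_iter,
        "n_observations": results.model.n,
        "components": comp.to_dict(orient="records"),
        "dropped_fixed_columns": results.model.dropped_fixed,
    }
    if results.vc.ai_inverse is not None:
        payload["ai_inverse"] = {
            "labels": list(results.vc.ai_inverse.index),
            "values": results.vc.ai_inverse.to_numpy().tolist(),
        }
    if extra:
        payload.update(extra)
    write_json(payload, path)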