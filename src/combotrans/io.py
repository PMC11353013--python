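"""CSV/YAML readers and writers for combination matrices and configs.

Wide dialect: first row holds the drug-B doses (µM), first column the drug-A
doses; cell [i, j] is relative viability, with "0" marking the untreated
margin. Long dialect columns: cell_line, drug_a, dose_a_uM, drug_b,
dose_b_uM, viability, replicate (replicates are averaged on read).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dose_response import CombinationMatrix
from .errors import FormatError

__all__ = [
    "read_combination_csv",
    "write_combination_csv",
    "load_config",
    "write_manifest",
    "file_sha256",
]

LONG_COLUMNS = ["cell_line", "drug_a", "dose_a_uM", "drug_b", "dose_b_uM",
                "viability", "replicate"]


def _read_wide(path: Path, **meta) -> CombinationMatrix:
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse wide CSV: {exc}") from exc
    try:
        doses_a = df.index.to_numpy(dtype=float)
        doses_b = df.columns.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed header — dose axes must be numeric "
                          f"(row labels {list(df.index)[:3]}...)") from exc
    values = df.to_numpy(dtype=float)
    if values.ndim != 2 or np.any(pd.isna(values)):
        raise FormatError(f"{path}: wide matrix is non-rectangular or has gaps")
    if np.unique(doses_a).size != doses_a.size or np.unique(doses_b).size != doses_b.size:
        raise FormatError(f"{path}: duplicate dose levels in wide matrix")
    return CombinationMatrix(
        drug_a_name=meta.get("drug_a", "drug_a"),
        drug_b_name=meta.get("drug_b", "drug_b"),
        doses_a=doses_a, doses_b=doses_b, viability=values,
        cell_line=meta.get("cell_line", ""),
        treatment_hours=meta.get("treatment_hours", 120.0),
    )


def _read_long(path: Path, **meta) -> CombinationMatrix:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse long CSV: {exc}") from exc
    missing = [c for c in LONG_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: long CSV missing columns {missing}")
    agg = (df.groupby(["dose_a_uM", "dose_b_uM"])["viability"].mean().unstack())
    if agg.isna().any().any():
        raise FormatError(f"{path}: long CSV does not cover a full dose grid")
    return CombinationMatrix(
        drug_a_name=meta.get("drug_a", str(df["drug_a"].iloc[0])),
        drug_b_name=meta.get("drug_b", str(df["drug_b"].iloc[0])),
        doses_a=agg.index.to_numpy(dtype=float),
        doses_b=agg.columns.to_numpy(dtype=float),
        viability=agg.to_numpy(dtype=float),
        cell_line=meta.get("cell_line", str(df["cell_line"].iloc[0])),
        treatment_hours=meta.get("treatment_hours", 120.0),
    )


def read_combination_csv(path, dialect: str = "wide", **meta) -> CombinationMatrix:
    """Read and validate a combination matrix from CSV."""
    path = Path(path)
    if dialect == "wide":
        m = _read_wide(path, **meta)
    elif dialect == "long":
        m = _read_long(path, **meta)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    m.validate()
    return m


def write_combination_csv(matrix: CombinationMatrix, path) -> None:
    """Write a combination matrix in the wide CSV dialect."""
    df = pd.DataFrame(matrix.viability,
                      index=matrix.doses_a, columns=matrix.doses_b)
    df.index.name = f"{matrix.drug_a_name}_uM"
    df.to_csv(path)


def load_config(path) -> dict:
    """Load a YAML (or JSON) analysis configuration."""
    path = Path(path)
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, stage: str, inputs: dict, seeds: dict,
                   outputs: list) -> Path:
    """Record stage provenance: inputs, seeds, and output hashes."""
    from . import __version__
    out_dir = Path(out_dir)
    manifest = {
        "stage": stage,
        "version": __version__,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "seeds": seeds,
        "outputs": {str(Path(p).name): file_sha256(p) for p in outputs},
    }
    path = out_dir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
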