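"""Readers, writers, configuration and run manifests.

All writers are deterministic: JSON keys are sorted and floats are written
at 10 significant digits, so repeated runs of the same inputs diff clean.
Tables are tab-separated text; the expression matrix is genes x samples
with gene symbols in the first column and sample ids in the header.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import AdaptiveLassoConfig, PairSignature
from .pairs import GenePairSet, validate_expression
from .pipeline import PipelineConfig
from .survival import REQUIRED_CLINICAL_COLUMNS, validate_clinical
from .synthetic import SimulationConfig

SIGNATURE_SCHEMA_VERSION = 1
FLOAT_FORMAT = "%.10g"


def _round10(x):
    """Canonical float at 10 significant digits (stable across runs)."""
    return float(f"{float(x):.10g}")


def _canonical(obj):
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return _round10(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _canonical(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(_canonical(obj), indent=2, sort_keys=True) + "\n"
    )


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV matrix; duplicate gene symbols and
    non-numeric cells are hard errors naming the offending location."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate gene symbol in {path}: {dup!r}")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            gene = raw.index[bad][0]
            raise ValueError(
                f"non-numeric expression value in {path} at gene {gene!r}, "
                f"sample {col!r}"
            )
        values[:, j] = converted.to_numpy()
    expr = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    expr.index.name = raw.index.name or "gene"
    return validate_expression(expr)


def write_expression(expr: pd.DataFrame, path) -> None:
    validate_expression(expr)
    out = expr.copy()
    out.index.name = out.index.name or "gene"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV (sample_id, time_months, event, optional
    covariates)."""
    table = pd.read_csv(path, sep="\t")
    if "sample_id" not in table.columns:
        raise ValueError(f"clinical table {path} is missing column 'sample_id'")
    for col in REQUIRED_CLINICAL_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"clinical table {path} is missing column {col!r}")
    table = table.set_index("sample_id")
    return validate_clinical(table)


def write_clinical(clinical: pd.DataFrame, path) -> None:
    validate_clinical(clinical)
    out = clinical.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_gene_list(path) -> list[str]:
    genes = [line.strip() for line in Path(path).read_text().splitlines()]
    genes = [g for g in genes if g and not g.startswith("#")]
    if len(set(genes)) != len(genes):
        raise ValueError(f"duplicate gene symbol in gene list {path}")
    return genes


def write_signature(signature: PairSignature, path) -> None:
    payload = {
        "schema_version": SIGNATURE_SCHEMA_VERSION,
        "software_version": __version__,
        "pairs": [list(p) for p in signature.pairs.pairs],
        "coefficients": list(signature.coefficients),
        "lambda_selected": signature.lambda_selected,
        "ridge_lambda": signature.ridge_lambda,
        "ridge_betas": {k: v for k, v in signature.ridge_betas.items()},
        "n_folds": signature.n_folds,
        "fold_seed": signature.fold_seed,
        "weight_cap": signature.weight_cap,
        "selection_rule": signature.selection_rule,
        "stage_counts": signature.stage_counts,
    }
    write_json(payload, path)


def read_signature(path) -> PairSignature:
    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != SIGNATURE_SCHEMA_VERSION:
        raise ValueError(
            f"signature schema version {version!r} is not supported "
            f"(expected {SIGNATURE_SCHEMA_VERSION})"
        )
    ridge = payload.get("ridge_betas", {})
    return PairSignature(
        pairs=GenePairSet(tuple(tuple(p) for p in payload["pairs"]),
                          provenance="loaded signature"),
        coefficients=np.asarray(payload["coefficients"], dtype=float),
        lambda_selected=float(payload["lambda_selected"]),
        ridge_lambda=float(payload.get("ridge_lambda", float("nan"))),
        ridge_betas=pd.Series(ridge, dtype=float, name="ridge_beta"),
        n_folds=int(payload["n_folds"]),
        fold_seed=int(payload["fold_seed"]),
        weight_cap=float(payload["weight_cap"]),
        selection_rule=str(payload["selection_rule"]),
        stage_counts=dict(payload.get("stage_counts", {})),
    )


def write_pair_matrix(matrix, path) -> None:
    out = matrix.scores.copy()
    out.index.name = "pair"
    out.to_csv(path, sep="\t")


def write_scores(scores: pd.Series, path, group=None) -> None:
    frame = scores.rename("lrgpi").to_frame()
    if group is not None:
        frame["group"] = group
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_scores(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if "sample_id" not in table.columns or "lrgpi" not in table.columns:
        raise ValueError(f"score table {path} must have sample_id and lrgpi columns")
    return table.set_index("sample_id")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record emitted once per pipeline run."""

    command: str
    config: dict
    inputs: dict = field(default_factory=dict)    # name -> sha256
    stage_counts: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    software_version: str = __version__
    python_version: str = field(default_factory=platform.python_version)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        write_json(self.__dict__, path)


# ---------------------------------------------------------------------------
# YAML configuration


def _dataclass_update(obj, data: dict, name: str):
    for key, val in data.items():
        if not hasattr(obj, key):
            raise ValueError(f"unknown {name} option {key!r}")
        setattr(obj, key, val)
    return obj


def pipeline_config_from_dict(data: dict | None) -> PipelineConfig:
    data = dict(data or {})
    adaptive = AdaptiveLassoConfig()
    _dataclass_update(adaptive, data.pop("adaptive", {}), "adaptive-LASSO")
    cfg = PipelineConfig(adaptive=adaptive)
    if "evaluation_horizons" in data:
        data["evaluation_horizons"] = tuple(float(h) for h in data["evaluation_horizons"])
    _dataclass_update(cfg, data, "pipeline")
    return cfg.validate()


def simulation_config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    planted = [tuple(p) for p in data.pop("planted_pairs", [])]
    cfg = SimulationConfig(
        n_genes=int(data.pop("n_genes")),
        n_samples=int(data.pop("n_samples")),
        planted_pairs=[(int(a), int(b), float(c)) for a, b, c in planted],
    )
    for key in ("gene_means", "gene_sds"):
        if key in data:
            data[key] = np.asarray(data[key], dtype=float)
    _dataclass_update(cfg, data, "simulation")
    return cfg.validate()


def load_config(path) -> dict:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data
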