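"""Delimited-text readers/writers and run manifests.

All on-disk formats are headered delimited text (comma by default, tab
accepted): a feature table with ``sample_id`` (plus optional ``line_id`` and
``group``) columns followed by one column per analyte; a pedigree with
``hybrid_id, female_id, male_id, population``; phenotypes with
``hybrid_id, tgw``; marker lists with ``analyte_id, vip``; train/validation
splits with ``hybrid_id, role``.  Readers validate schemas and report the
offending row/column; write-then-read is an identity (floats are written
with 12 significant digits).
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (FeatureTable, MarkerSet, PredictionReport,
                         TrainingComposition, validate_pedigree)

FLOAT_FORMAT = "%.12g"

__all__ = [
    "read_feature_table", "write_feature_table",
    "read_pedigree", "write_pedigree",
    "read_phenotypes", "write_phenotypes",
    "read_markers", "write_markers",
    "read_split", "write_split",
    "write_report", "read_report",
    "write_truth", "write_manifest",
]

_META_COLUMNS = ("sample_id", "line_id", "group")


def _delimiter(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def _check_header(path, delimiter) -> list:
    with open(path, newline="", encoding="utf-8") as handle:
        header = next(csv.reader(handle, delimiter=delimiter))
    seen = set()
    for name in header:
        if name in seen:
            raise ValueError(f"{path}: duplicate column {name!r}")
        seen.add(name)
    return header


def _numeric_block(frame: pd.DataFrame, path) -> pd.DataFrame:
    """Parse all cells to floats, reporting the first bad coordinate."""
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~frame.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {frame.iat[i, j]!r} at row "
            f"{frame.index[i]!r}, column {frame.columns[j]!r}")
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing value at row {frame.index[i]!r}, "
                         f"column {frame.columns[j]!r}")
    return numeric.astype(float)


def read_feature_table(path) -> FeatureTable:
    """Load a feature table; ``line_id``/``group`` columns are optional."""
    delimiter = _delimiter(path)
    header = _check_header(path, delimiter)
    if "sample_id" not in header:
        raise ValueError(f"{path}: missing 'sample_id' column")
    frame = pd.read_csv(path, sep=delimiter, dtype=str,
                        keep_default_na=False, na_values=[])
    frame = frame.set_index("sample_id")
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    line_ids = frame.pop("line_id") if "line_id" in frame.columns else None
    groups = frame.pop("group") if "group" in frame.columns else None
    data = _numeric_block(frame, path)
    return FeatureTable(data, line_ids=line_ids, groups=groups)


def write_feature_table(table: FeatureTable, path) -> None:
    out = table.data.copy()
    if table.groups is not None:
        out.insert(0, "group", table.groups)
    if table.line_ids is not None:
        out.insert(0, "line_id", table.line_ids)
    out.index.name = "sample_id"
    out.to_csv(path, sep=_delimiter(path), float_format=FLOAT_FORMAT)


def read_pedigree(path, known_lines=None) -> pd.DataFrame:
    pedigree = pd.read_csv(path, sep=_delimiter(path), dtype=str)
    validate_pedigree(pedigree)
    if known_lines is not None:
        known = set(known_lines)
        for row in pedigree.itertuples(index=False):
            for parent in (row.female_id, row.male_id):
                if parent not in known:
                    raise ValueError(
                        f"{path}: hybrid {row.hybrid_id!r} references "
                        f"unknown parent {parent!r}")
    return pedigree


def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    validate_pedigree(pedigree).to_csv(path, sep=_delimiter(path), index=False)


def read_phenotypes(path) -> pd.Series:
    frame = pd.read_csv(path, sep=_delimiter(path))
    for column in ("hybrid_id", "tgw"):
        if column not in frame.columns:
            raise ValueError(f"{path}: missing {column!r} column")
    if frame["hybrid_id"].duplicated().any():
        dup = frame.loc[frame["hybrid_id"].duplicated(), "hybrid_id"].iloc[0]
        raise ValueError(f"{path}: duplicate hybrid id {dup!r}")
    tgw = pd.to_numeric(frame["tgw"], errors="coerce")
    if tgw.isna().any():
        bad = frame.loc[tgw.isna(), "hybrid_id"].iloc[0]
        raise ValueError(f"{path}: non-numeric TGW for hybrid {bad!r}")
    if (tgw <= 0).any():
        bad = frame.loc[tgw <= 0, "hybrid_id"].iloc[0]
        raise ValueError(f"{path}: TGW must be positive (hybrid {bad!r})")
    return pd.Series(tgw.to_numpy(), index=pd.Index(frame["hybrid_id"],
                     name="hybrid_id"), name="tgw")


def write_phenotypes(phenotypes: pd.Series, path) -> None:
    frame = phenotypes.rename("tgw").rename_axis("hybrid_id").reset_index()
    frame.to_csv(path, sep=_delimiter(path), index=False,
                 float_format=FLOAT_FORMAT)


def read_markers(path) -> MarkerSet:
    frame = pd.read_csv(path, sep=_delimiter(path))
    for column in ("analyte_id", "vip"):
        if column not in frame.columns:
            raise ValueError(f"{path}: missing {column!r} column")
    vip = pd.Series(frame["vip"].to_numpy(dtype=float),
                    index=frame["analyte_id"], name="vip")
    threshold = float(frame["vip_threshold"].iloc[0]) \
        if "vip_threshold" in frame.columns else float("nan")
    return MarkerSet(list(frame["analyte_id"]), threshold, vip)


def write_markers(markers: MarkerSet, path) -> None:
    frame = pd.DataFrame({
        "analyte_id": markers.analyte_ids,
        "vip": [markers.vip_values[a] for a in markers.analyte_ids],
        "vip_threshold": markers.vip_threshold,
    })
    frame.to_csv(path, sep=_delimiter(path), index=False,
                 float_format=FLOAT_FORMAT)


def read_split(path) -> TrainingComposition:
    frame = pd.read_csv(path, sep=_delimiter(path))
    for column in ("hybrid_id", "role"):
        if column not in frame.columns:
            raise ValueError(f"{path}: missing {column!r} column")
    bad = frame.loc[~frame["role"].isin(["train", "validation"]), "role"]
    if len(bad):
        raise ValueError(f"{path}: unknown role {bad.iloc[0]!r}")
    name = str(frame["composition"].iloc[0]) if "composition" in frame.columns \
        else Path(path).stem
    return TrainingComposition(
        name=name,
        train_ids=frame.loc[frame["role"] == "train", "hybrid_id"].tolist(),
        validation_ids=frame.loc[frame["role"] == "validation",
                                 "hybrid_id"].tolist(),
    )


def write_split(split: TrainingComposition, path) -> None:
    frame = pd.DataFrame({
        "hybrid_id": list(split.train_ids) + list(split.validation_ids),
        "role": ["train"] * len(split.train_ids)
                + ["validation"] * len(split.validation_ids),
        "composition": split.name,
    })
    frame.to_csv(path, sep=_delimiter(path), index=False)


def write_report(report: PredictionReport, path) -> None:
    frame = report.hybrids.copy()
    frame["composition"] = report.composition_name
    frame["n_markers"] = report.n_markers
    frame["n_components"] = report.n_components
    frame.to_csv(path, sep=_delimiter(path), float_format=FLOAT_FORMAT)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_delimiter(path), index_col="hybrid_id")


def write_truth(truth, path) -> None:
    payload = {
        "causal_analyte_ids": list(truth.causal_analyte_ids),
        "causal_effects": np.asarray(truth.causal_effects, float).tolist(),
        "intercept": float(truth.intercept),
        "env_offsets": {str(k): float(v) for k, v in truth.env_offsets.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def write_manifest(path, config: dict, seed: int, inputs: dict | None = None) -> None:
    """Machine-readable record of a run, enabling byte-identical replays."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": int(seed),
        "inputs": {},
    }
    for name, input_path in (inputs or {}).items():
        digest = hashlib.sha256(Path(input_path).read_bytes()).hexdigest()
        manifest["inputs"][name] = {"path": str(input_path), "sha256": digest}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str),
                          encoding="utf-8")
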