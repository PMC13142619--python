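"""TSV/CSV dialects for matrices, covariates, outcomes and annotations.

The native dialect is TSV (feature counts can exceed 1e5 columns and values
never need quoting); CSV is accepted on read, chosen by file extension.
Matrices are written samples-as-rows with a leading ``sample_id`` column;
a transpose flag on read handles the features-as-rows exports common in
methylation tooling.  Empty cells and the token ``NA`` encode missing
values.  Write -> read round-trips are lossless to 1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import COVARIATE_COLUMNS, FeatureMatrix, OrdinalOutcome, validate_covariates
from .integration import AnnotationMap

__all__ = ["read_matrix", "write_matrix", "read_covariates", "write_covariates",
           "read_outcome", "write_outcome", "read_annotations",
           "read_replicate_table", "write_replicate_table",
           "RunConfig", "load_config", "check_alignment"]

_FLOAT_FMT = "%.12g"


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_table(path, index_col: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), na_values=["NA", ""],
                     keep_default_na=False)
    if df.columns[0] != index_col:
        raise ValueError(f"{path}: first column must be {index_col!r}, "
                         f"got {df.columns[0]!r}")
    if df[index_col].duplicated().any():
        dup = df[index_col][df[index_col].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate {index_col} values: {dup[:5]}")
    return df.set_index(index_col)


def read_matrix(path, layer: str, transpose: bool = False) -> FeatureMatrix:
    """Read a feature matrix (samples as rows unless ``transpose``)."""
    index_col = "feature_id" if transpose else "sample_id"
    df = _read_table(path, index_col)
    non_numeric = df.columns[~df.dtypes.map(
        lambda t: np.issubdtype(t, np.number))].tolist()
    if non_numeric:
        raise ValueError(f"{path}: non-numeric columns: {non_numeric[:5]}")
    if transpose:
        df = df.T
        df.index.name = "sample_id"
        df.columns.name = "feature_id"
    else:
        df.columns.name = "feature_id"
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate ids after transpose")
    return FeatureMatrix(df.astype(float), layer)


def write_matrix(m: FeatureMatrix, path) -> None:
    df = m.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep(path), na_rep="NA", float_format=_FLOAT_FMT)


def read_covariates(path) -> pd.DataFrame:
    df = _read_table(path, "sample_id")
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: covariate columns missing: {missing}")
    df = df[list(COVARIATE_COLUMNS)]
    for c in ("sex", "race", "education"):
        df[c] = df[c].astype(int)
    return validate_covariates(df)


def write_covariates(cov: pd.DataFrame, path) -> None:
    out = cov.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=_sep(path), float_format=_FLOAT_FMT)


def read_outcome(path, levels: list[str]) -> OrdinalOutcome:
    df = _read_table(path, "sample_id")
    if "outcome" not in df.columns:
        raise ValueError(f"{path}: expected an 'outcome' column")
    return OrdinalOutcome.from_labels(df["outcome"].astype(str), levels)


def write_outcome(outcome: OrdinalOutcome, path) -> None:
    out = outcome.labels().rename("outcome").to_frame()
    out.index.name = "sample_id"
    out.to_csv(path, sep=_sep(path))


def read_replicate_table(path) -> pd.DataFrame:
    return _read_table(path, "feature_id")


def write_replicate_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep=_sep(path), float_format=_FLOAT_FMT)


def read_annotations(feature_entity_path, entity_pathway_path) -> AnnotationMap:
    fe = pd.read_csv(feature_entity_path, sep=_sep(feature_entity_path))
    ep = pd.read_csv(entity_pathway_path, sep=_sep(entity_pathway_path))
    return AnnotationMap(fe, ep)


def check_alignment(*indexed, names=None) -> None:
    """Raise with an explicit mismatch listing when sample sets differ."""
    sets = [set(obj.index if hasattr(obj, "index") else obj) for obj in indexed]
    names = names or [f"input{i}" for i in range(len(sets))]
    base = sets[0]
    for nm, s in zip(names[1:], sets[1:]):
        if s != base:
            only_a = sorted(base - s)[:5]
            only_b = sorted(s - base)[:5]
            raise ValueError(
                f"sample misalignment between {names[0]} and {nm}: "
                f"only in {names[0]}: {only_a}; only in {nm}: {only_b}")


@dataclass
class RunConfig:
    """Declarative configuration of a pipeline run."""

    out_dir: str
    dnam_path: str | None = None
    metab_path: str | None = None
    covariates_path: str | None = None
    outcome_path: str | None = None
    outcome_kind: str = "ABC"
    methods: list[str] = field(default_factory=lambda: ["PT", "RF"])
    layers: list[str] = field(default_factory=lambda: ["dnam", "metabolome",
                                                       "combined"])
    forms: list[str] | None = None
    seeds: list[int] | None = None
    base_seed: int = 0
    n_seeds: int = 10
    train_fraction: float = 0.5
    scope: str = "train-fitted"     # imputation/standardization scope
    method_config: dict = field(default_factory=dict)

    def seed_list(self) -> list[int]:
        if self.seeds is not None:
            return [int(s) for s in self.seeds]
        return [self.base_seed + i for i in range(self.n_seeds)]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    data = {k: getattr(config, k) for k in RunConfig.__dataclass_fields__}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
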