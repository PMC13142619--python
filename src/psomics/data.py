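"""Core in-memory containers shared by every pipeline stage.

All containers are thin, typed wrappers around pandas objects so they can be
written to and read from plain TSV without loss.  Samples are always rows,
features always columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAYERS = ("dnam", "metabolome", "combined")

#: columns a covariate table must provide, in canonical order
COVARIATE_COLUMNS = ("age", "sex", "race", "education", "adi", "pmi")

#: outcome level labels, ordered from least to most severe pathology
OUTCOME_LEVELS = {
    "ABC": ["none", "low", "intermediate", "high"],
    "Braak": ["stage1", "stage2", "stage3", "stage4", "stage5", "stage6"],
    "CERAD": ["none", "sparse", "moderate", "frequent"],
}


@dataclass
class FeatureMatrix:
    """Samples x features matrix for one omics layer.

    Missing values are encoded as NaN in ``data``; ``layer`` tags the omics
    source.  DNA-methylation beta values live in [0, 1] until standardized.
    """

    data: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dup}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(self.data.isna().any().any())

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "FeatureMatrix":
        return FeatureMatrix(self.data.loc[sample_ids], self.layer)

    def subset_features(self, feature_ids) -> "FeatureMatrix":
        return FeatureMatrix(self.data.loc[:, list(feature_ids)], self.layer)


@dataclass
class OrdinalOutcome:
    """Ordered categorical outcome: level labels plus integer codes 0..L-1."""

    levels: list[str]
    codes: pd.Series  # int codes per sample, indexed by sample id

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if codes.size and (codes.min() < 0 or codes.max() >= len(self.levels)):
            raise ValueError("outcome codes outside declared level range")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def sample_ids(self) -> pd.Index:
        return self.codes.index

    def labels(self) -> pd.Series:
        return self.codes.map(dict(enumerate(self.levels)))

    def subset(self, sample_ids) -> "OrdinalOutcome":
        return OrdinalOutcome(list(self.levels), self.codes.loc[sample_ids])

    @classmethod
    def from_labels(cls, labels: pd.Series, levels: list[str]) -> "OrdinalOutcome":
        unknown = sorted(set(labels) - set(levels))
        if unknown:
            raise ValueError(f"undeclared outcome levels: {unknown}")
        mapping = {lv: i for i, lv in enumerate(levels)}
        return cls(list(levels), labels.map(mapping).astype(int))


def validate_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Check a covariate table against the expected schema."""
    missing = [c for c in COVARIATE_COLUMNS if c not in cov.columns]
    if missing:
        raise ValueError(f"covariate table lacks columns: {missing}")
    if cov[list(COVARIATE_COLUMNS)].isna().any().any():
        bad = cov.columns[cov.isna().any()].tolist()
        raise ValueError(f"covariates contain missing values in: {bad}")
    edu = set(pd.unique(cov["education"]))
    if not edu <= {0, 1, 2}:
        raise ValueError(f"education must be coded 0/1/2, got {sorted(edu)}")
    return cov


def covariate_design(cov: pd.DataFrame) -> pd.DataFrame:
    """Expand a covariate table into a numeric design matrix.

    Education (3 ordered levels) enters as two indicator columns; continuous
    covariates (age, ADI, PMI) are z-scored for numerical conditioning, which
    leaves all likelihoods, Wald and LR tests invariant.
    """
    cov = validate_covariates(cov)
    design = pd.DataFrame(index=cov.index)
    for col in ("age", "adi", "pmi"):
        x = cov[col].astype(float)
        sd = x.std(ddof=0)
        design[col] = (x - x.mean()) / sd if sd > 0 else 0.0
    design["sex"] = cov["sex"].astype(float)
    design["race"] = cov["race"].astype(float)
    design["edu_college"] = (cov["education"] == 1).astype(float)
    design["edu_graduate"] = (cov["education"] == 2).astype(float)
    return design


@dataclass
class SplitSpec:
    """A single train/test partition of the sample ids."""

    seed: int
    fraction: float
    train_ids: list
    test_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


@dataclass
class MultiOmicsDataset:
    """The linked inputs of one analysis: two layers, covariates, outcome.

    Layers may cover different (overlapping) sample sets; covariates and the
    outcome must cover the union.
    """

    dnam: FeatureMatrix | None
    metab: FeatureMatrix | None
    covariates: pd.DataFrame
    outcome: OrdinalOutcome

    def __post_init__(self) -> None:
        validate_covariates(self.covariates)
        want = set(self.covariates.index)
        for fm in (self.dnam, self.metab):
            if fm is None:
                continue
            extra = set(fm.sample_ids) - want
            if extra:
                raise ValueError(
                    f"{fm.layer} samples missing covariates: {sorted(extra)[:5]}"
                )
        if set(self.outcome.sample_ids) != want:
            raise ValueError("outcome and covariate sample ids differ")

    def layer(self, name: str) -> FeatureMatrix:
        if name == "dnam" and self.dnam is not None:
            return self.dnam
        if name == "metabolome" and self.metab is not None:
            return self.metab
        raise KeyError(f"dataset has no layer {name!r}")

    @property
    def shared_samples(self) -> pd.Index:
        """Samples observed in every available layer."""
        idx = None
        for fm in (self.dnam, self.metab):
            if fm is None:
                continue
            idx = fm.sample_ids if idx is None else idx.intersection(fm.sample_ids)
        if idx is None:
            raise ValueError("dataset has no omics layers")
        return idx
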