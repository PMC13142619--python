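"""Profile-score computation and ordinal evaluation on test samples.

A profile score is the weighted sum PS_i = sum_k beta_k m_ik over the
selected features.  Evaluation fits proportional-odds models on the test
samples:

    single : outcome ~ PS_layer + covariates
    multi  : outcome ~ PS_combined + covariates
    joint  : outcome ~ PS_dnam + PS_metabolome + covariates
    joint+interaction : adds PS_dnam * PS_metabolome

and reports the partial McFadden R^2 = 1 - llf_full / llf_covariates_only
together with a likelihood-ratio test of the PS terms (df = number of PS
terms entering the full model).  PS terms are z-scored before entry so
interaction coefficients are comparable across seeds; a constant PS is
dropped from the model and from the df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .data import FeatureMatrix
from .ordinal import OrderedLogitResults, fit_propodds
from .selection import WeightSet

__all__ = ["ScoreVector", "EvalResult", "compute_ps", "evaluate", "ps_correlation"]

FORMS = ("single", "multi", "joint", "joint_interaction")


@dataclass
class ScoreVector:
    """Per-sample profile score with a reference to its weight set."""

    scores: pd.Series
    source: WeightSet

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.index


@dataclass
class EvalResult:
    """Outcome of one test-set evaluation."""

    form: str
    fit: OrderedLogitResults | None
    llf_full: float
    llf_reduced: float
    partial_r2: float
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    k: int                      # number of features in the underlying PS
    significant: bool

    def row(self, **extra) -> dict:
        d = {"form": self.form, "partial_r2": self.partial_r2,
             "lrt_stat": self.lrt_stat, "lrt_df": self.lrt_df,
             "lrt_p": self.lrt_p, "K": self.k, "significant": self.significant}
        d.update(extra)
        return d


def compute_ps(m: FeatureMatrix, w: WeightSet) -> ScoreVector:
    """PS_i = sum_k beta_k m_ik over the weight set's features.

    ``m`` must be on the scale the weights were trained on (standardized
    where the method standardized).  An empty weight set yields all-zero
    scores with a warning.
    """
    if w.k == 0:
        warnings.warn(f"empty weight set ({w.method}/{w.layer}): PS is zero",
                      RuntimeWarning)
        return ScoreVector(pd.Series(0.0, index=m.sample_ids, name="PS"), w)
    missing = [f for f in w.weights.index if f not in m.data.columns]
    if missing:
        raise KeyError(f"features absent from matrix: {missing[:5]}")
    vals = m.data.loc[:, w.weights.index].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("matrix has missing values among scored features")
    ps = vals @ w.weights.to_numpy()
    return ScoreVector(pd.Series(ps, index=m.sample_ids, name="PS"), w)


def _standardize_ps(s: pd.Series) -> pd.Series | None:
    sd = s.std(ddof=0)
    if not np.isfinite(sd) or sd == 0:
        return None
    return (s - s.mean()) / sd


def evaluate(form: str, outcome, covariates: pd.DataFrame,
             ps_dnam: ScoreVector | None = None,
             ps_metab: ScoreVector | None = None,
             ps_combined: ScoreVector | None = None,
             alpha: float = 0.05) -> EvalResult:
    """Fit the requested PS model and the covariates-only reduction on the
    same samples; report partial R^2 and the likelihood-ratio test."""
    if form not in FORMS:
        raise ValueError(f"unknown form {form!r}; expected one of {FORMS}")
    if form == "single":
        provided = [s for s in (ps_dnam, ps_metab, ps_combined) if s is not None]
        if len(provided) != 1:
            raise ValueError("single form takes exactly one score vector")
        terms = {"PS": provided[0].scores}
        k = provided[0].source.k
    elif form == "multi":
        if ps_combined is None:
            raise ValueError("multi form requires ps_combined")
        terms = {"PS_combined": ps_combined.scores}
        k = ps_combined.source.k
    else:
        if ps_dnam is None or ps_metab is None:
            raise ValueError(f"{form} requires both layer score vectors")
        terms = {"PS_dnam": ps_dnam.scores, "PS_metab": ps_metab.scores}
        k = ps_dnam.source.k + ps_metab.source.k

    codes = outcome.codes
    idx = codes.index
    cov = covariates.loc[idx]
    used = {}
    for name, s in terms.items():
        if not s.index.equals(idx):
            if set(s.index) != set(idx):
                raise ValueError(f"sample misalignment in {name}")
            s = s.loc[idx]
        z = _standardize_ps(s)
        if z is None:
            warnings.warn(f"{name} is constant; dropped from the {form} model",
                          RuntimeWarning)
        else:
            used[name] = z
    if form == "joint_interaction" and {"PS_dnam", "PS_metab"} <= set(used):
        used["PS_dnam:PS_metab"] = used["PS_dnam"] * used["PS_metab"]

    reduced = fit_propodds(cov.to_numpy(dtype=float), outcome)
    llf_reduced = reduced.llf
    if not used:
        return EvalResult(form, None, llf_reduced, llf_reduced, 0.0, 0.0, 0,
                          1.0, k, False)
    X_full = pd.DataFrame(used, index=idx).join(cov)
    full = fit_propodds(X_full, outcome)
    llf_full = full.llf
    df = len(used)
    stat = max(0.0, 2.0 * (llf_full - llf_reduced))
    p = float(chi2.sf(stat, df))
    r2 = 1.0 - llf_full / llf_reduced if llf_reduced != 0 else 0.0
    return EvalResult(form, full, llf_full, llf_reduced, float(r2), float(stat),
                      df, p, k, bool(p < alpha))


def ps_correlation(a: ScoreVector, b: ScoreVector) -> float:
    """Pearson correlation of two profile scores over their shared samples."""
    shared = a.sample_ids.intersection(b.sample_ids)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples")
    x = a.scores.loc[shared].to_numpy()
    y = b.scores.loc[shared].to_numpy()
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: a score has zero variance")
    return float(np.corrcoef(x, y)[0, 1])
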