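"""Metabolomics QC, replicate averaging, imputation, scaling, splitting.

QC follows the standard LC-HRMS feature-screening rules: a feature is kept
only if it is detected in more than 15% of samples, its median technical
coefficient of variation is below 30%, and its technical replicates agree
with Pearson rho above 0.7.  Surviving features are averaged across non-zero
replicates and log2-transformed.

Per-sample CV is defined as SD/mean of the non-zero replicates (requiring at
least two), and replicate agreement as the median of the three pairwise
Pearson correlations computed over samples where both replicates are
non-zero; both choices are robust to non-detected cells.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .data import FeatureMatrix, SplitSpec

__all__ = ["qc_filter_features", "impute_missing", "standardize",
           "unstandardize", "split_samples", "replicate_array"]


def replicate_array(table: pd.DataFrame) -> tuple[np.ndarray, list, pd.Index]:
    """Unpack a wide replicate table into (n_samples, p, 3) intensities.

    The table has one row per feature with optional ``mz``/``rt`` columns and
    intensity columns named ``<sample>_r1..r3``.
    """
    rep_cols = [c for c in table.columns if c not in ("mz", "rt")]
    samples: list = []
    for c in rep_cols:
        base, _, tag = c.rpartition("_")
        if tag not in ("r1", "r2", "r3") or not base:
            raise ValueError(f"malformed replicate column {c!r}")
        if base not in samples:
            samples.append(base)
    arr = np.empty((len(samples), table.shape[0], 3))
    for i, s in enumerate(samples):
        for r in range(3):
            col = f"{s}_r{r + 1}"
            if col not in table.columns:
                raise ValueError(f"sample {s!r} lacks replicate column {col!r}")
            arr[i, :, r] = table[col].to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("replicate intensities must be non-negative")
    return arr, samples, table.index


def _pair_correlations(reps: np.ndarray) -> np.ndarray:
    """Median over the 3 replicate pairs of Pearson rho across samples where
    both replicates are non-zero; NaN pairs (fewer than 3 shared samples or
    zero variance) are ignored, all-NaN features return NaN."""
    n, p, _ = reps.shape
    out = np.full((p, 3), np.nan)
    pairs = ((0, 1), (0, 2), (1, 2))
    for k, (u, v) in enumerate(pairs):
        a, b = reps[:, :, u], reps[:, :, v]
        ok = (a > 0) & (b > 0)
        cnt = ok.sum(axis=0)
        aw = np.where(ok, a, np.nan)
        bw = np.where(ok, b, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            am = np.nanmean(aw, axis=0)
            bm = np.nanmean(bw, axis=0)
            ac = np.where(ok, a - am, 0.0)
            bc = np.where(ok, b - bm, 0.0)
            cov = (ac * bc).sum(axis=0)
            den = np.sqrt((ac ** 2).sum(axis=0) * (bc ** 2).sum(axis=0))
            rho = np.where((cnt >= 3) & (den > 0), cov / np.where(den > 0, den, 1.0),
                           np.nan)
        out[:, k] = rho
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(out, axis=1)


def qc_filter_features(table: pd.DataFrame, min_detect: float = 0.15,
                       max_cv: float = 0.30, min_rep_cor: float = 0.70,
                       ) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Screen replicate-level metabolomics features and average survivors.

    Returns the feature matrix of log2 mean non-zero-replicate intensities
    (cells with all replicates zero are missing) restricted to features that
    pass all three rules, plus a per-feature QC report with the computed
    statistics and pass flags.
    """
    if table.shape[0] == 0:
        raise ValueError("empty replicate table")
    reps, samples, feature_ids = replicate_array(table)
    n, p, _ = reps.shape
    if n < 2:
        raise ValueError("QC needs at least 2 samples")

    nonzero = reps > 0
    detect = nonzero.any(axis=2).mean(axis=0)  # fraction of samples detected

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        k = nonzero.sum(axis=2).astype(float)
        s = np.where(nonzero, reps, 0.0).sum(axis=2)
        mean_nz = np.where(k > 0, s / np.where(k > 0, k, 1.0), np.nan)
        dev2 = np.where(nonzero, (reps - mean_nz[:, :, None]) ** 2, 0.0).sum(axis=2)
        sd_nz = np.where(k >= 2, np.sqrt(dev2 / np.maximum(k - 1.0, 1.0)), np.nan)
        cv = sd_nz / mean_nz  # NaN where < 2 non-zero replicates
        median_cv = np.nanmedian(np.where(k >= 2, cv, np.nan), axis=0)

    rep_cor = _pair_correlations(reps)

    pass_detect = detect > min_detect
    pass_cv = median_cv < max_cv  # NaN compares False -> fail
    pass_cor = rep_cor > min_rep_cor
    keep = pass_detect & pass_cv & pass_cor

    report = pd.DataFrame({
        "detection_rate": detect, "median_cv": median_cv, "replicate_cor": rep_cor,
        "pass_detection": pass_detect, "pass_cv": pass_cv, "pass_correlation": pass_cor,
        "retained": keep,
    }, index=feature_ids)

    with np.errstate(divide="ignore", invalid="ignore"):
        avg = np.where(k > 0, np.log2(mean_nz), np.nan)
    data = pd.DataFrame(avg[:, keep], index=pd.Index(samples, name="sample_id"),
                        columns=feature_ids[keep])
    return FeatureMatrix(data, "metabolome"), report


def split_samples(sample_ids, seed: int, fraction: float = 0.5) -> SplitSpec:
    """Uniform random train/test partition; |train| = round(fraction * n)."""
    ids = list(sample_ids)
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if len(ids) < 4:
        raise ValueError("need at least 4 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(fraction * len(ids)))
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return SplitSpec(seed=seed, fraction=fraction, train_ids=train, test_ids=test)


def impute_missing(m: FeatureMatrix, scope: str = "train-fitted",
                   split: SplitSpec | None = None, seed: int = 0,
                   n_estimators: int = 50, max_iter: int = 10,
                   tol: float = 1e-4) -> FeatureMatrix:
    """Iterative random-forest imputation (missRanger-style).

    Features are swept in decreasing-missingness order; for each, a random
    forest regressor is trained on all other features over rows where the
    feature is observed, and its missing cells are predicted.  Sweeps repeat
    until the mean absolute change of imputed cells falls below ``tol`` or
    ``max_iter`` sweeps.  In ``train-fitted`` scope the forests see training
    rows only (then predict test cells too); ``global`` scope uses all rows.
    Observed cells are never altered.  Deterministic given ``seed``.
    """
    if not m.has_missing:
        return m
    if m.layer != "metabolome":
        raise ValueError(f"missing values in non-metabolome layer {m.layer!r}")
    if scope not in ("train-fitted", "global"):
        raise ValueError(f"unknown imputation scope {scope!r}")
    if scope == "train-fitted" and split is None:
        raise ValueError("train-fitted scope requires a split")

    df = m.data.copy()
    miss = df.isna()
    fully = miss.all(axis=0)
    if fully.any():
        raise ValueError(f"feature fully missing: {df.columns[fully].tolist()}")

    fit_rows = (df.index.isin(split.train_ids) if scope == "train-fitted"
                else np.ones(len(df), dtype=bool))
    X = df.to_numpy(dtype=float)
    miss_np = miss.to_numpy()
    col_means = np.nanmean(np.where(fit_rows[:, None], X, np.nan), axis=0)
    col_means = np.where(np.isnan(col_means), np.nanmean(X, axis=0), col_means)
    X = np.where(miss_np, col_means[None, :], X)

    order = np.argsort(-miss_np.sum(axis=0), kind="stable")
    order = [j for j in order if miss_np[:, j].any()]
    rng = np.random.default_rng(seed)
    for sweep in range(max_iter):
        total_change, n_cells = 0.0, 0
        for j in order:
            rows_fit = fit_rows & ~miss_np[:, j]
            if rows_fit.sum() < 2:
                raise ValueError(f"feature {df.columns[j]!r} has too few observed "
                                 "rows in the fitting scope")
            others = np.delete(np.arange(X.shape[1]), j)
            rf = RandomForestRegressor(
                n_estimators=n_estimators, max_features="sqrt", n_jobs=1,
                random_state=int(rng.integers(2 ** 31)))
            rf.fit(X[np.ix_(rows_fit, others)], X[rows_fit, j])
            pred = rf.predict(X[np.ix_(miss_np[:, j], others)])
            total_change += float(np.abs(pred - X[miss_np[:, j], j]).sum())
            n_cells += int(miss_np[:, j].sum())
            X[miss_np[:, j], j] = pred
        if n_cells == 0 or total_change / n_cells < tol:
            break
    out = pd.DataFrame(X, index=df.index, columns=df.columns)
    return FeatureMatrix(out, m.layer)


def standardize(m: FeatureMatrix, split: SplitSpec | None = None,
                ) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Z-score every feature using training-sample mean and SD.

    Returns the standardized matrix (all samples) and a stats table with the
    means/SDs used, which :func:`unstandardize` inverts exactly.  Features
    with zero training variance are dropped with a warning.
    """
    if m.has_missing:
        raise ValueError("standardize requires a complete matrix (impute first)")
    train = m.data.loc[split.train_ids] if split is not None else m.data
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all features have zero training variance")
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance features: "
                      f"{m.data.columns[~keep].tolist()[:5]}...", RuntimeWarning)
    data = (m.data.loc[:, keep] - mean[keep]) / sd[keep]
    stats = pd.DataFrame({"mean": mean[keep], "sd": sd[keep]})
    return FeatureMatrix(data, m.layer), stats


def unstandardize(m: FeatureMatrix, stats: pd.DataFrame) -> FeatureMatrix:
    """Invert :func:`standardize` for the retained features."""
    data = m.data * stats["sd"] + stats["mean"]
    return FeatureMatrix(data, m.layer)
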