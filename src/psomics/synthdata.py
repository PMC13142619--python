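"""Synthetic two-layer omics data with known ground truth.

The generator emulates the statistical structure of a brain-bank multi-omics
study of Alzheimer's-disease neuropathology: a DNA-methylation layer (beta
values in (0,1)), a log2-scale metabolomics layer, demographic covariates,
and an ordered neuropathology outcome (ABC score, Braak stage or CERAD
score).  The outcome is produced by a latent-liability mechanism,

    y* = sum_j beta_j x~_j + sum_l gamma_l m~_l + c' z + eps,

with standardized features x~/m~, covariate design z, and *logistic* noise
eps, so that the proportional-odds model is exactly the data-generating
model and parameter-recovery tests are sharp.  Thresholds are placed at
empirical quantiles of y* so the target class frequencies are hit for any
effect configuration.

Covariate and outcome marginals default to the study population the package
targets: age at death ~ N(76.4, 10.0) truncated to [57, 105], 54.8% male,
10.8% Black, education (22.3, 49.7, 28.0)%, ADI ~ N(36.1, 24.0) truncated to
[1, 94], PMI lognormal matched to mean 11.6 h and SD 9.6 h clipped to
[1.5, 64], and ABC class frequencies (9.6, 17.8, 13.4, 59.2)%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FeatureMatrix, MultiOmicsDataset, OrdinalOutcome, OUTCOME_LEVELS, covariate_design

__all__ = ["SimConfig", "SyntheticTruth", "generate_dataset",
           "generate_replicate_table", "DEFAULT_CLASS_PROBS"]

#: outcome level frequencies observed in the target study population (n=157)
DEFAULT_CLASS_PROBS = {
    "ABC": np.array([15, 28, 21, 93], dtype=float) / 157,
    "Braak": np.array([16, 11, 17, 18, 21, 74], dtype=float) / 157,
    "CERAD": np.array([34, 3, 10, 110], dtype=float) / 157,
}

#: small non-zero covariate effects (on the z-scored design columns
#: age, adi, pmi, sex, race, edu_college, edu_graduate) so covariate
#: adjustment is non-trivial by default
DEFAULT_COVARIATE_EFFECTS = np.array([0.30, 0.10, 0.05, 0.15, 0.10, 0.10, 0.10])


@dataclass
class SimConfig:
    """Configuration of one synthetic dataset.

    Defaults are desk-scale: the real study has ~790k CpGs and ~35k
    metabolite features on 157 donors; here the feature counts are scaled to
    what a laptop CPU can sweep while preserving n ~ 160 and the blockwise
    correlation structure of omics data.
    """

    n_samples: int = 160
    p_dnam: int = 2000
    p_metab: int = 1000
    n_causal_dnam: int = 10
    n_causal_metab: int = 10
    effect_sd: float = 0.5
    block_size: int = 10
    block_rho: float = 0.3
    outcome_kind: str = "ABC"
    class_probs: np.ndarray | None = None
    covariate_effects: np.ndarray = field(
        default_factory=lambda: DEFAULT_COVARIATE_EFFECTS.copy())
    missing_rate_metab: float = 0.0
    replicate_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outcome_kind not in OUTCOME_LEVELS:
            raise ValueError(f"unknown outcome kind {self.outcome_kind!r}")
        if self.class_probs is None:
            self.class_probs = DEFAULT_CLASS_PROBS[self.outcome_kind].copy()
        self.class_probs = np.asarray(self.class_probs, dtype=float)
        L = len(OUTCOME_LEVELS[self.outcome_kind])
        if self.class_probs.size != L:
            raise ValueError(
                f"class_probs has {self.class_probs.size} entries but "
                f"{self.outcome_kind} has {L} levels")
        if abs(self.class_probs.sum() - 1.0) > 1e-12:
            raise ValueError("class_probs must sum to 1")
        for name in ("n_samples", "p_dnam", "p_metab", "block_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(self.n_causal_dnam, self.n_causal_metab) < 0:
            raise ValueError("causal feature counts must be non-negative")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValueError("block_rho must be in [0, 1)")
        if not 0.0 <= self.missing_rate_metab <= 1.0:
            raise ValueError("missing_rate_metab must be in [0, 1]")
        if self.effect_sd < 0 or self.replicate_cv < 0:
            raise ValueError("effect_sd and replicate_cv must be non-negative")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    causal_features: list[tuple[str, str, float]]  # (layer, feature id, effect)
    latent_liability: pd.Series
    linear_predictor: pd.Series  # liability minus the logistic noise
    thresholds_used: np.ndarray
    latent_features: dict[str, pd.DataFrame]  # standardized features per layer

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.causal_features,
                            columns=["layer", "feature_id", "effect"])


def _block_features(rng: np.random.Generator, n: int, p: int, block_size: int,
                    rho: float) -> np.ndarray:
    """Standardized latent features in equicorrelated blocks."""
    out = np.empty((n, p))
    for start in range(0, p, block_size):
        width = min(block_size, p - start)
        shared = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, width))
        out[:, start:start + width] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise
    return out


def _truncated_normal(rng, n, mean, sd, lo, hi):
    x = rng.normal(mean, sd, size=n)
    while True:
        bad = (x < lo) | (x > hi)
        if not bad.any():
            return x
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))


def _draw_covariates(rng: np.random.Generator, n: int, index) -> pd.DataFrame:
    # lognormal parameters matched by moments to mean 11.6, SD 9.6
    s2 = np.log(1.0 + (9.6 / 11.6) ** 2)
    mu = np.log(11.6) - s2 / 2.0
    return pd.DataFrame({
        "age": _truncated_normal(rng, n, 76.4, 10.0, 57.0, 105.0),
        "sex": (rng.random(n) < 0.548).astype(int),     # 1 = male
        "race": (rng.random(n) < 0.108).astype(int),    # 1 = Black
        "education": rng.choice(3, size=n, p=[0.223, 0.497, 0.280]),
        "adi": _truncated_normal(rng, n, 36.1, 24.0, 1.0, 94.0),
        "pmi": np.clip(rng.lognormal(mu, np.sqrt(s2), size=n), 1.5, 64.0),
    }, index=index)


def generate_dataset(config: SimConfig) -> tuple[
        FeatureMatrix, FeatureMatrix, pd.DataFrame, OrdinalOutcome, SyntheticTruth]:
    """Generate one linked synthetic dataset; bit-identical under a fixed seed.

    Returns (dnam, metab, covariates, outcome, truth).  DNAm values are a
    logit-normal transform of the standardized latent features (strictly
    inside (0, 1)); metabolite values are on the log2 scale; the outcome is
    cut from the latent liability at empirical quantiles matching
    ``class_probs``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    samples = pd.Index([f"S{i:04d}" for i in range(cfg.n_samples)], name="sample_id")
    dnam_ids = pd.Index([f"cg{i:06d}" for i in range(cfg.p_dnam)], name="feature_id")
    metab_ids = pd.Index([f"met{i:05d}" for i in range(cfg.p_metab)], name="feature_id")

    x_dnam = _block_features(rng, cfg.n_samples, cfg.p_dnam, cfg.block_size, cfg.block_rho)
    x_metab = _block_features(rng, cfg.n_samples, cfg.p_metab, cfg.block_size, cfg.block_rho)

    # observable scales: logit-normal betas for DNAm, log2 intensities for metab
    mu_cpg = rng.uniform(-3.0, 3.0, size=cfg.p_dnam)
    dnam_obs = 1.0 / (1.0 + np.exp(-(mu_cpg[None, :] + 0.5 * x_dnam)))
    mu_met = rng.uniform(12.0, 24.0, size=cfg.p_metab)
    sd_met = rng.uniform(0.5, 1.5, size=cfg.p_metab)
    metab_obs = mu_met[None, :] + sd_met[None, :] * x_metab

    cov = _draw_covariates(rng, cfg.n_samples, samples)
    z = covariate_design(cov).to_numpy()
    ceff = np.asarray(cfg.covariate_effects, dtype=float)
    if ceff.size != z.shape[1]:
        raise ValueError(
            f"covariate_effects has {ceff.size} entries, design has {z.shape[1]}")

    causal: list[tuple[str, str, float]] = []
    lin = z @ ceff
    for layer, ids, x, k in (("dnam", dnam_ids, x_dnam, cfg.n_causal_dnam),
                             ("metabolome", metab_ids, x_metab, cfg.n_causal_metab)):
        if k > x.shape[1]:
            raise ValueError(f"n_causal exceeds p for layer {layer}")
        pick = rng.choice(x.shape[1], size=k, replace=False)
        # fixed magnitude, random sign: SD of the planted effects equals
        # effect_sd while every planted feature is genuinely causal
        effects = cfg.effect_sd * rng.choice([-1.0, 1.0], size=k)
        lin = lin + x[:, pick] @ effects
        causal.extend((layer, ids[j], float(b)) for j, b in zip(pick, effects))

    liability = lin + rng.logistic(size=cfg.n_samples)
    cum = np.cumsum(cfg.class_probs)[:-1]
    thresholds = np.quantile(liability, cum)
    codes = (liability[:, None] > thresholds[None, :]).sum(axis=1)

    metab_df = pd.DataFrame(metab_obs, index=samples, columns=metab_ids)
    if cfg.missing_rate_metab > 0:
        mask = rng.random(metab_df.shape) < cfg.missing_rate_metab
        # never blank out an entire feature
        full = mask.all(axis=0)
        mask[0, full] = False
        metab_df = metab_df.mask(mask)

    truth = SyntheticTruth(
        causal_features=causal,
        latent_liability=pd.Series(liability, index=samples, name="liability"),
        linear_predictor=pd.Series(lin, index=samples, name="linear_predictor"),
        thresholds_used=thresholds,
        latent_features={
            "dnam": pd.DataFrame(x_dnam, index=samples, columns=dnam_ids),
            "metabolome": pd.DataFrame(x_metab, index=samples, columns=metab_ids),
        },
    )
    outcome = OrdinalOutcome(OUTCOME_LEVELS[cfg.outcome_kind],
                             pd.Series(codes, index=samples, name="outcome"))
    dnam = FeatureMatrix(pd.DataFrame(dnam_obs, index=samples, columns=dnam_ids), "dnam")
    metab = FeatureMatrix(metab_df, "metabolome")
    return dnam, metab, cov, outcome, truth


def make_dataset(config: SimConfig) -> tuple[MultiOmicsDataset, SyntheticTruth]:
    """Bundle :func:`generate_dataset` output into a MultiOmicsDataset."""
    dnam, metab, cov, outcome, truth = generate_dataset(config)
    return MultiOmicsDataset(dnam, metab, cov, outcome), truth


def generate_replicate_table(metab: FeatureMatrix, config: SimConfig,
                             nondetect_rate: float = 0.02,
                             n_fail_detection: int = 0,
                             n_fail_cv: int = 0,
                             n_fail_correlation: int = 0) -> pd.DataFrame:
    """Raw triplicate LC-MS-style intensity table derived from a clean
    metabolite matrix.

    Each log2 value becomes three raw intensities ``2**value`` perturbed by
    multiplicative lognormal noise with coefficient of variation
    ``config.replicate_cv``; a ``nondetect_rate`` fraction of sample-feature
    cells is zeroed ("not detected").  Optionally, the first features are
    deliberately broken so each QC rule has known failures:

    - fail-detection: detected in at most 10% of samples,
    - fail-cv: replicate noise inflated to CV 1.0,
    - fail-correlation: replicates shuffled across samples (pairwise rho ~ 0).

    Returns the wide table (one row per feature: feature_id, mz, rt, then
    ``<sample>_r1..r3`` columns) with the planted failures recorded in
    ``table.attrs['planted_failures']``.
    """
    if config.replicate_cv < 0:
        raise ValueError("replicate_cv must be non-negative")
    if metab.has_missing:
        raise ValueError("replicate generation requires a complete matrix")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5eb]))
    vals = 2.0 ** metab.values()  # n x p raw intensities
    n, p = vals.shape
    n_flag = n_fail_detection + n_fail_cv + n_fail_correlation
    if n_flag > p:
        raise ValueError("more planted failures than features")

    cv = np.full(p, float(config.replicate_cv))
    fail_det = list(range(0, n_fail_detection))
    fail_cv = list(range(n_fail_detection, n_fail_detection + n_fail_cv))
    fail_cor = list(range(n_fail_detection + n_fail_cv, n_flag))
    cv[fail_cv] = 1.0

    sigma = np.sqrt(np.log1p(cv ** 2))  # zero CV -> noise factor exactly 1
    reps = np.empty((n, p, 3))
    for r in range(3):
        noise = np.exp(rng.normal(0.0, 1.0, size=(n, p)) * sigma[None, :])
        reps[:, :, r] = vals * noise

    if nondetect_rate > 0:
        mask = rng.random((n, p, 3)) < nondetect_rate
        reps[mask] = 0.0
    for j in fail_det:
        detected = rng.permutation(n)[: max(1, int(np.floor(0.10 * n)))]
        drop = np.ones(n, dtype=bool)
        drop[detected] = False
        reps[drop, j, :] = 0.0
    for j in fail_cor:
        reps[:, j, 1] = reps[rng.permutation(n), j, 1]
        reps[:, j, 2] = reps[rng.permutation(n), j, 2]

    cols: dict[str, np.ndarray] = {
        "mz": np.round(rng.uniform(70.0, 1200.0, size=p), 4),
        "rt": np.round(rng.uniform(10.0, 600.0, size=p), 2),
    }
    for i, s in enumerate(metab.sample_ids):
        for r in range(3):
            cols[f"{s}_r{r + 1}"] = reps[i, :, r]
    table = pd.DataFrame(cols, index=metab.feature_ids.rename("feature_id"))
    table.attrs["planted_failures"] = {
        "detection": [metab.feature_ids[j] for j in fail_det],
        "cv": [metab.feature_ids[j] for j in fail_cv],
        "correlation": [metab.feature_ids[j] for j in fail_cor],
    }
    return table
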