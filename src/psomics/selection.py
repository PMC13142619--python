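"""Weight estimation: the five methods that turn training data into a
profile-score weight set.

Every method maps (training features, outcome, covariates, seed) to a
:class:`WeightSet` of (feature, weight) pairs; the profile score of a sample
is then the weighted sum of its feature values.  Methods never see test
samples.  The methods are:

PT  - pruning (correlation-based hierarchical clustering to representatives)
      followed by thresholding (per-feature covariate-adjusted ordinal
      regression, keep Wald p < alpha, weight = slope);
EN  - ordinal elastic net: proportional-odds likelihood with an L1/L2
      penalty on feature slopes (thresholds and covariates unpenalized),
      lambda chosen by cross-validated deviance;
BO  - component-wise linear boosting of the cumulative-logit loss with
      threshold re-optimization and early stopping on a validation split;
RF  - random-forest permutation variable importance (out-of-bag,
      ranger-style), signed by the marginal Spearman direction;
WA  - windowed cross-leverage screening: within sliding feature windows the
      off-diagonal entries of the projection onto the top right-singular
      subspace of [X_w, y] link each feature to the outcome.

Combinations (PT+EN, WA+EN) run the first method as a feature filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestRegressor
from sklearn.ensemble._forest import _generate_unsampled_indices

from .data import FeatureMatrix, OrdinalOutcome
from .ordinal import OrderedLogit, null_thresholds

__all__ = ["WeightSet", "PruneResult", "prune", "threshold_select",
           "fit_ordinal_elasticnet", "fit_ordinal_boosting", "fit_rf_vim",
           "cross_leverage_screen", "compose", "estimate_weights"]


@dataclass
class WeightSet:
    """(feature, weight) pairs defining one profile score."""

    method: str
    layer: str
    weights: pd.Series  # indexed by feature id; finite, non-zero
    seed: int | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = self.weights
        if w.index.has_duplicates:
            raise ValueError("duplicate feature ids in weight set")
        if w.size and (~np.isfinite(w.to_numpy())).any():
            raise ValueError("non-finite weights")
        self.weights = w[w != 0.0].astype(float)

    @property
    def k(self) -> int:
        return int(self.weights.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "method": self.method, "layer": self.layer,
            "seed": -1 if self.seed is None else self.seed,
            "feature_id": self.weights.index, "weight": self.weights.to_numpy(),
        })


def _empty_weights(method, layer, seed, **prov) -> WeightSet:
    return WeightSet(method, layer, pd.Series(dtype=float, name="weight"),
                     seed=seed, provenance=prov)


def _codes(outcome) -> np.ndarray:
    return np.asarray(getattr(outcome, "codes", outcome), dtype=int)


# --------------------------------------------------------------------------
# PT: pruning
# --------------------------------------------------------------------------

@dataclass
class PruneResult:
    n_clusters: int
    assignment: pd.Series            # cluster label per feature id
    representatives: list            # one feature id per cluster


def prune(train: FeatureMatrix, n_clusters: int,
          distance: str = "one-minus-abs-cor") -> PruneResult:
    """Complete-linkage hierarchical clustering of features on correlation
    distance, cut to ``n_clusters``; the representative of each cluster is
    its medoid (the feature with the highest mean |rho| to co-members),
    ties broken by lexicographic feature id.
    """
    p = train.n_features
    if n_clusters > p:
        raise ValueError(f"n_clusters={n_clusters} exceeds p={p}")
    if n_clusters < 1:
        raise ValueError("n_clusters must be positive")
    X = train.values()
    if np.isnan(X).any():
        raise ValueError("prune requires a complete matrix")
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = train.feature_ids[sd == 0].tolist()
        raise ValueError(f"zero-variance features must be dropped upstream: {bad[:5]}")
    ids = list(train.feature_ids)
    if p == 1:
        return PruneResult(1, pd.Series([1], index=train.feature_ids), ids)
    corr = np.corrcoef(X, rowvar=False)
    if distance == "one-minus-abs-cor":
        sim = np.abs(corr)
    elif distance == "one-minus-cor":
        sim = corr
    else:
        raise ValueError(f"unknown prune distance {distance!r}")
    d = np.clip(1.0 - sim, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    labels = fcluster(linkage(squareform(d, checks=False), method="complete"),
                      t=n_clusters, criterion="maxclust")
    reps = []
    abs_corr = np.abs(corr)
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if members.size == 1:
            reps.append(ids[members[0]])
            continue
        sub = abs_corr[np.ix_(members, members)]
        mean_rho = (sub.sum(axis=1) - 1.0) / (members.size - 1)
        order = sorted(range(members.size), key=lambda i: (-mean_rho[i], ids[members[i]]))
        reps.append(ids[members[order[0]]])
    return PruneResult(int(np.unique(labels).size),
                       pd.Series(labels, index=train.feature_ids), reps)


# --------------------------------------------------------------------------
# thresholding
# --------------------------------------------------------------------------

def threshold_select(train: FeatureMatrix, outcome, covariates: pd.DataFrame,
                     alpha: float = 0.05, seed: int | None = None) -> WeightSet:
    """Per-feature covariate-adjusted proportional-odds association scan.

    Keeps features whose slope Wald p-value is below ``alpha``; the weight is
    the fitted slope (covariate coefficients are discarded).
    """
    y = _codes(outcome)
    Z = covariates.to_numpy(dtype=float)
    n_levels = int(getattr(outcome, "n_levels", y.max() + 1))
    # warm start from the covariate-only fit
    base = OrderedLogit(y, Z, n_levels=n_levels).fit()
    L = base.model.n_levels
    t0 = np.insert(base.transformed_params, L - 1, 0.0)
    X = train.values()
    kept_ids, kept_w = [], []
    for j, fid in enumerate(train.feature_ids):
        exog = np.column_stack([X[:, j], Z])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", RuntimeWarning)
                res = OrderedLogit(y, exog, n_levels=n_levels).fit(start_params=t0)
        except (RuntimeWarning, np.linalg.LinAlgError):
            warnings.warn(f"threshold scan: fit failed for {fid}, skipped",
                          RuntimeWarning)
            continue
        if not res.converged:
            warnings.warn(f"threshold scan: non-convergent fit for {fid}, skipped",
                          RuntimeWarning)
            continue
        if res.pvalues[0] < alpha:
            kept_ids.append(fid)
            kept_w.append(float(res.params[0]))
    return WeightSet("threshold", train.layer,
                     pd.Series(kept_w, index=pd.Index(kept_ids, name="feature_id"),
                               name="weight"),
                     seed=seed, provenance={"alpha": alpha})


# --------------------------------------------------------------------------
# EN: ordinal elastic net
# --------------------------------------------------------------------------

def _prox_fit(model: OrderedLogit, n_pen: int, lam: float, alpha_mix: float,
              t0: np.ndarray, maxiter: int = 400, tol: float = 1e-7) -> np.ndarray:
    """Proximal-gradient minimization of
    -loglik/n + lam * (alpha*||b||_1 + (1-alpha)/2*||b||_2^2)
    where the penalty applies to the first ``n_pen`` slopes only.
    Thresholds enter via the monotone transform; L2 is kept in the smooth
    part so only soft-thresholding is needed in the prox.
    """
    n = model.nobs
    L = model.n_levels
    sl = slice(L - 1, L - 1 + n_pen)  # penalized slope block

    def smooth(t):
        ll, g = model.loglike_grad_t(t)
        b = t[sl]
        f = -ll / n + 0.5 * lam * (1.0 - alpha_mix) * float(b @ b)
        g = -g / n
        g[sl] += lam * (1.0 - alpha_mix) * b
        return f, g

    t = t0.copy()
    f, g = smooth(t)
    step = 1.0
    thr = lam * alpha_mix
    for _ in range(maxiter):
        while True:
            cand = t - step * g
            cand[sl] = np.sign(cand[sl]) * np.maximum(np.abs(cand[sl]) - step * thr, 0.0)
            delta = cand - t
            f_new, g_new = smooth(cand)
            if f_new <= f + float(g @ delta) + float(delta @ delta) / (2 * step) + 1e-12:
                break
            step *= 0.5
            if step < 1e-12:
                break
        move = float(np.max(np.abs(delta))) if delta.size else 0.0
        t, f, g = cand, f_new, g_new
        step = min(step * 2.0, 1.0)
        if move < tol:
            break
    return t


def fit_ordinal_elasticnet(train: FeatureMatrix, outcome, covariates: pd.DataFrame,
                           alpha_mix: float = 0.5, lambda_path=None,
                           n_lambda: int = 50, lambda_min_ratio: float = 1e-4,
                           cv_folds: int = 5, seed: int = 0,
                           maxiter: int = 400) -> WeightSet:
    """Elastic-net penalized proportional-odds regression.

    Feature slopes carry the penalty ``lambda * (alpha*L1 + (1-alpha)/2*L2)``
    (on the mean-log-likelihood scale); thresholds and covariate slopes are
    unpenalized.  A decreasing lambda path from the data-derived lambda_max
    is solved with warm starts, lambda is chosen by ``cv_folds``-fold
    cross-validated deviance within the training data, and the returned
    weights are the non-zero feature slopes at the chosen lambda.
    """
    y = _codes(outcome)
    n_levels = int(getattr(outcome, "n_levels", y.max() + 1))
    Xf = train.values()
    Z = covariates.to_numpy(dtype=float)
    p = Xf.shape[1]
    exog = np.column_stack([Xf, Z])

    def make_model(rows):
        return OrderedLogit(y[rows], exog[rows], n_levels=n_levels, ridge_eps=0.0)

    all_rows = np.arange(y.size)
    model = make_model(all_rows)
    L = model.n_levels

    # start at the null-plus-covariates optimum, feature slopes zero
    base = OrderedLogit(y, Z, n_levels=n_levels).fit()
    t0 = np.concatenate([base.transformed_params[:L - 1], np.zeros(p),
                         base.transformed_params[L - 1:]])
    _, g = model.loglike_grad_t(t0)
    grad_f = -g[L - 1:L - 1 + p] / model.nobs
    lam_max = float(np.max(np.abs(grad_f))) / max(alpha_mix, 1e-3)
    if lambda_path is None:
        lambda_path = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    else:
        lambda_path = np.asarray(lambda_path, dtype=float)
        if np.any(np.diff(lambda_path) >= 0):
            raise ValueError("lambda_path must be strictly decreasing")

    def solve_path(rows):
        m = make_model(rows)
        Lm = m.n_levels
        thr0 = null_thresholds(np.bincount(m.endog, minlength=Lm))
        t = np.concatenate([[thr0[0]], np.log(np.maximum(np.diff(thr0), 1e-8)),
                            np.zeros(p), base.transformed_params[L - 1:]])
        sols = []
        for lam in lambda_path:
            t = _prox_fit(m, p, lam, alpha_mix, t, maxiter=maxiter)
            sols.append(t.copy())
        return m, sols

    # cross-validated deviance
    rng = np.random.default_rng(seed)
    perm = rng.permutation(y.size)
    folds = np.array_split(perm, cv_folds)
    dev = np.zeros((cv_folds, lambda_path.size))
    for i, hold in enumerate(folds):
        fit_rows = np.setdiff1d(perm, hold)
        m, sols = solve_path(fit_rows)
        remap = np.full(n_levels, -1)
        remap[m._kept_levels] = np.arange(m.n_levels)
        yh = remap[y[hold]]
        ok = yh >= 0  # held-out levels unseen in the fold are skipped
        for k, t in enumerate(sols):
            thr, beta = m._unpack(t)
            ev = OrderedLogit.__new__(OrderedLogit)
            ev.endog, ev.n_levels = yh[ok], m.n_levels
            ev.exog = exog[hold][ok]
            ev.k_exog, ev.nobs = ev.exog.shape[1], int(ok.sum())
            dev[i, k] = -2.0 * OrderedLogit.loglike(ev, thr, beta)
    best = int(np.argmin(dev.mean(axis=0)))

    _, sols = solve_path(all_rows)
    thr, beta = model._unpack(sols[best])
    w = pd.Series(beta[:p], index=train.feature_ids.rename("feature_id"),
                  name="weight")
    return WeightSet("EN", train.layer, w[w != 0], seed=seed, provenance={
        "alpha_mix": alpha_mix, "lambda": float(lambda_path[best]),
        "lambda_max": lam_max, "cv_folds": cv_folds, "n_lambda": int(lambda_path.size),
    })


# --------------------------------------------------------------------------
# BO: component-wise ordinal boosting
# --------------------------------------------------------------------------

def fit_ordinal_boosting(train: FeatureMatrix, outcome, covariates: pd.DataFrame,
                         nu: float = 0.1, mstop: int = 500,
                         val_fraction: float = 0.25, seed: int = 0) -> WeightSet:
    """Component-wise linear boosting of the cumulative-logit loss.

    Starts from the null-model thresholds with all slopes zero.  Each
    iteration regresses the negative loss gradient (w.r.t. the linear
    predictor) on every candidate column (features and covariates) by simple
    least squares, advances the single best-fitting component by ``nu`` times
    its fit, then re-optimizes each threshold with a damped one-dimensional
    Newton step.  Training loss is enforced non-increasing by step halving.
    With ``val_fraction > 0`` an internal validation split picks the
    iteration with minimal held-out deviance; the returned weights are the
    accumulated non-zero feature coefficients at that iteration.
    """
    if mstop < 0:
        raise ValueError("mstop must be non-negative")
    y_all = _codes(outcome)
    n_levels_declared = int(getattr(outcome, "n_levels", y_all.max() + 1))
    Xf = train.values()
    Z = covariates.to_numpy(dtype=float)
    cols = np.column_stack([Xf, Z])
    p = Xf.shape[1]
    names = list(train.feature_ids) + list(covariates.columns)
    n = y_all.size

    rng = np.random.default_rng(seed)
    if val_fraction > 0:
        n_val = max(1, int(round(val_fraction * n)))
        perm = rng.permutation(n)
        val_rows, fit_rows = perm[:n_val], perm[n_val:]
    else:
        fit_rows, val_rows = np.arange(n), np.empty(0, dtype=int)

    # renumber levels jointly so fit and validation share a coding
    kept = np.flatnonzero(np.bincount(y_all[fit_rows], minlength=n_levels_declared) > 0)
    remap = np.full(n_levels_declared, -1)
    remap[kept] = np.arange(kept.size)
    Lf = kept.size
    if Lf < 2:
        raise ValueError("boosting training split has fewer than 2 outcome levels")
    y = remap[y_all[fit_rows]]
    Xfit = cols[fit_rows]
    y_val = remap[y_all[val_rows]] if val_rows.size else np.empty(0, dtype=int)
    vok = y_val >= 0
    y_val, X_val = y_val[vok], (cols[val_rows][vok] if val_rows.size else cols[:0])

    def loss_only(thr, beta, X, yy):
        m = OrderedLogit.__new__(OrderedLogit)
        m.endog, m.n_levels = yy, Lf
        m.exog, m.k_exog, m.nobs = X, X.shape[1], yy.size
        return -OrderedLogit.loglike(m, thr, beta)

    thr = null_thresholds(np.bincount(y, minlength=Lf))
    beta = np.zeros(cols.shape[1])
    den = (Xfit ** 2).sum(axis=0)
    den = np.where(den > 0, den, np.inf)
    cur_loss = loss_only(thr, beta, Xfit, y)
    history: list[tuple[int, float, np.ndarray]] = []
    val_dev = []
    train_losses = [cur_loss]

    for _ in range(int(mstop)):
        # negative gradient of the loss wrt the linear predictor
        eta_grad = _eta_gradient(thr, beta, Xfit, y, Lf)
        num = Xfit.T @ eta_grad
        scores = num ** 2 / den
        j = int(np.argmax(scores))
        step_c = nu * num[j] / den[j]
        halve = 0
        while halve < 40:
            beta[j] += step_c
            new_loss = loss_only(thr, beta, Xfit, y)
            if new_loss <= cur_loss + 1e-12:
                break
            beta[j] -= step_c
            step_c *= 0.5
            halve += 1
        else:
            break
        # damped diagonal Newton step on each threshold
        thr, new_loss = _threshold_newton(thr, beta, Xfit, y, Lf, new_loss, loss_only)
        cur_loss = new_loss
        train_losses.append(cur_loss)
        history.append((j, beta[j], thr.copy()))
        if val_rows.size:
            val_dev.append(2.0 * loss_only(thr, beta, X_val, y_val))

    if val_rows.size and val_dev:
        best = int(np.argmin(val_dev)) + 1  # iterations are 1-based
    else:
        best = len(history)

    final = np.zeros(cols.shape[1])
    for j, accum, _ in history[:best]:
        final[j] = accum  # later entries overwrite: accumulated value at that iter
    w = pd.Series(final[:p], index=train.feature_ids.rename("feature_id"),
                  name="weight")
    losses = np.asarray(train_losses)
    assert np.all(np.diff(losses) <= 1e-9), "boosting training loss increased"
    return WeightSet("BO", train.layer, w[w != 0], seed=seed, provenance={
        "nu": nu, "mstop": int(mstop), "mstop_used": best,
        "val_fraction": val_fraction, "train_losses": losses,
    })


def _eta_gradient(thr, beta, X, y, L):
    """d loglik / d eta per observation (the boosting working response)."""
    from scipy.special import expit
    eta = X @ beta
    ext = np.concatenate(([-np.inf], thr, [np.inf]))
    a, b = ext[y + 1] - eta, ext[y] - eta
    A, B = expit(a), expit(b)
    pr = np.clip(A - B, 1e-300, None)
    fA = np.where(np.isfinite(a), A * (1 - A), 0.0)
    fB = np.where(np.isfinite(b), B * (1 - B), 0.0)
    return (fB - fA) / pr


def _threshold_newton(thr, beta, X, y, L, cur_loss, loss_only):
    """One damped Newton step per threshold (keeps order, never increases
    the loss)."""
    from scipy.special import expit
    eta = X @ beta
    ext = np.concatenate(([-np.inf], thr, [np.inf]))
    a, b = ext[y + 1] - eta, ext[y] - eta
    A, B = expit(a), expit(b)
    pr = np.clip(A - B, 1e-300, None)
    fA = np.where(np.isfinite(a), A * (1 - A), 0.0)
    fB = np.where(np.isfinite(b), B * (1 - B), 0.0)
    fpA = np.where(np.isfinite(a), fA * (1 - 2 * A), 0.0)
    fpB = np.where(np.isfinite(b), fB * (1 - 2 * B), 0.0)
    grad = np.zeros(L - 1)
    hess = np.zeros(L - 1)
    for l in range(L - 1):
        up = y == l       # a_i uses theta_l
        dn = y == l + 1   # b_i uses theta_l
        grad[l] = (fA[up] / pr[up]).sum() - (fB[dn] / pr[dn]).sum()
        hess[l] = ((fpA[up] * pr[up] - fA[up] ** 2) / pr[up] ** 2).sum() \
            + ((-fpB[dn] * pr[dn] - fB[dn] ** 2) / pr[dn] ** 2).sum()
    step = np.where(hess < 0, -grad / hess, 0.0)  # ascent step on loglik
    scale = 1.0
    for _ in range(30):
        cand = thr + scale * step
        if np.all(np.diff(cand) > 0) or cand.size == 1:
            new_loss = loss_only(cand, beta, X, y)
            if new_loss <= cur_loss + 1e-12:
                return cand, new_loss
        scale *= 0.5
    return thr, cur_loss


# --------------------------------------------------------------------------
# RF: permutation variable importance
# --------------------------------------------------------------------------

def fit_rf_vim(train: FeatureMatrix, outcome, covariates: pd.DataFrame,
               n_trees: int = 1000, seed: int = 0,
               max_features="sqrt") -> WeightSet:
    """Random-forest weights: out-of-bag permutation variable importance.

    A regression forest on the integer-coded outcome (preserving order) over
    features plus covariates; per tree, each used feature is permuted among
    that tree's out-of-bag samples and the increase in OOB mean squared error
    is accumulated (the classic Breiman/ranger permutation VIM), averaged
    over all trees.  Features with VIM > 0 are kept with weight
    VIM * sign(Spearman rho(feature, outcome)); covariates are discarded.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be positive")
    y = _codes(outcome).astype(float)
    Xf = train.values()
    Z = covariates.to_numpy(dtype=float)
    X = np.ascontiguousarray(np.column_stack([Xf, Z]), dtype=np.float32)
    p = Xf.shape[1]
    n = y.size
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=max_features, bootstrap=True,
        n_jobs=1, random_state=seed)
    forest.fit(X, y)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xf0]))
    vim = np.zeros(X.shape[1])
    for est in forest.estimators_:
        oob = _generate_unsampled_indices(est.random_state, n, n, None)
        if oob.size < 2:
            continue
        Xo = X[oob]
        base = est.tree_.predict(Xo).ravel()
        base_mse = float(np.mean((y[oob] - base) ** 2))
        used = np.unique(est.tree_.feature)
        used = used[used >= 0]
        for j in used:
            perm = rng.permutation(oob.size)
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            pred = est.tree_.predict(Xp).ravel()
            vim[j] += float(np.mean((y[oob] - pred) ** 2)) - base_mse
    vim /= n_trees

    signs = np.zeros(p)
    for j in range(p):
        if vim[j] > 0:
            rho = spearmanr(Xf[:, j], y).statistic
            signs[j] = np.sign(rho) if np.isfinite(rho) else 0.0
    w = pd.Series(np.where(vim[:p] > 0, vim[:p] * signs, 0.0),
                  index=train.feature_ids.rename("feature_id"), name="weight")
    return WeightSet("RF", train.layer, w[w != 0], seed=seed, provenance={
        "n_trees": n_trees, "max_features": str(max_features)})


# --------------------------------------------------------------------------
# WA: cross-leverage screening
# --------------------------------------------------------------------------

def cross_leverage_screen(train: FeatureMatrix, outcome,
                          window: int | None = None, stride: int | None = None,
                          q: int = 5, rank_r: int | None = None,
                          seed: int | None = None) -> WeightSet:
    """Windowed SVD cross-leverage screening.

    Features are taken in their stored (positional) order and covered by
    windows of ``window`` features (default 2 * n samples, stride = window,
    i.e. non-overlapping).  Within a window, Z is the column-standardized
    [X_w, y] matrix; with thin SVD Z = U D V' truncated to rank
    r = ``rank_r`` or min(n - 1, w + 1), the cross-leverage of feature j is
    c_j = (V V')_{j,y}, the projection-matrix entry linking the feature to
    the outcome column.  The ``q`` features with largest |c_j| per window are
    selected with weight c_j.
    """
    y = _codes(outcome).astype(float)
    X = train.values()
    n, p = X.shape
    if window is None:
        window = 2 * n
    if window < 1 or q < 1:
        raise ValueError("window and q must be positive")
    if stride is None:
        stride = window
    ys = (y - y.mean())
    sd = ys.std()
    if sd == 0:
        raise ValueError("outcome has zero variance")
    ys = ys / sd

    chosen: dict = {}
    for start in range(0, p, stride):
        cols = np.arange(start, min(start + window, p))
        w = cols.size
        Zc = X[:, cols] - X[:, cols].mean(axis=0)
        csd = Zc.std(axis=0)
        if (csd == 0).any():
            raise ValueError("zero-variance feature inside a window")
        Z = np.column_stack([Zc / csd, ys])
        if rank_r is not None:
            r = rank_r
            if r >= min(Z.shape):
                raise ValueError(
                    "cross-leverage projection is the identity (all scores "
                    "zero); use a larger window or a smaller rank_r")
        else:
            r = min(n - 1, w + 1)
            if start == 0 and r >= min(Z.shape):
                raise ValueError(
                    "cross-leverage projection is the identity (all scores "
                    "zero); use a larger window or a smaller rank_r")
            # short tail windows: truncate below full rank instead of failing
            r = min(r, min(Z.shape) - 1)
        _, _, Vt = np.linalg.svd(Z, full_matrices=False)
        V = Vt[:r].T  # (w+1) x r
        c = V[:-1] @ V[-1]
        order = sorted(range(w), key=lambda i: (-abs(c[i]), train.feature_ids[cols[i]]))
        for i in order[:min(q, w)]:
            fid = train.feature_ids[cols[i]]
            if fid not in chosen or abs(c[i]) > abs(chosen[fid]):
                chosen[fid] = float(c[i])
        if start + window >= p:
            break
    w_ser = pd.Series(chosen, name="weight")
    w_ser.index.name = "feature_id"
    return WeightSet("WA", train.layer, w_ser, seed=seed, provenance={
        "window": window, "stride": stride, "q": q, "rank_r": rank_r})


# --------------------------------------------------------------------------
# compositions and dispatch
# --------------------------------------------------------------------------

def default_n_clusters(p: int, n_train: int) -> int:
    return min(p, 5 * n_train)


def compose(chain: tuple[str, ...], train: FeatureMatrix, outcome,
            covariates: pd.DataFrame, seed: int = 0,
            config: dict | None = None) -> WeightSet:
    """Run a two-stage method chain: a feature filter then an estimator.

    Supported chains: ("PT",) - prune then threshold (the canonical PT
    method); ("PT", "EN") - prune then elastic net; ("WA", "EN") -
    cross-leverage screen then elastic net.
    """
    cfg = dict(config or {})
    tag = "+".join(chain) if len(chain) > 1 else ("PT" if chain == ("PT",) else chain[0])
    if chain not in (("PT",), ("PT", "EN"), ("WA", "EN")):
        raise ValueError(f"unsupported method chain {chain!r}")

    if chain[0] == "PT":
        n_clusters = cfg.get("n_clusters") or default_n_clusters(
            train.n_features, train.n_samples)
        pr = prune(train, n_clusters, distance=cfg.get("prune_distance",
                                                       "one-minus-abs-cor"))
        subset, stage1_prov = pr.representatives, {"n_clusters": pr.n_clusters}
    else:  # WA filter
        ws = cross_leverage_screen(train, outcome, window=cfg.get("window"),
                                   stride=cfg.get("stride"), q=cfg.get("q", 5),
                                   rank_r=cfg.get("rank_r"), seed=seed)
        subset, stage1_prov = list(ws.weights.index), {"wa_selected": ws.k}

    if not subset:
        warnings.warn(f"{tag}: empty intermediate feature set", RuntimeWarning)
        return _empty_weights(tag, train.layer, seed, stage1=stage1_prov)
    reduced = train.subset_features(subset)

    if len(chain) == 1:  # canonical PT = prune -> threshold
        inner = threshold_select(reduced, outcome, covariates,
                                 alpha=cfg.get("alpha", 0.05), seed=seed)
    else:
        inner = fit_ordinal_elasticnet(
            reduced, outcome, covariates, alpha_mix=cfg.get("alpha_mix", 0.5),
            n_lambda=cfg.get("n_lambda", 50),
            lambda_min_ratio=cfg.get("lambda_min_ratio", 1e-4),
            cv_folds=cfg.get("cv_folds", 5), seed=seed,
            maxiter=cfg.get("en_maxiter", 400))
    prov = {"stage1": stage1_prov, "stage2": inner.provenance}
    return WeightSet(tag, train.layer, inner.weights, seed=seed, provenance=prov)


METHODS = ("PT", "EN", "BO", "RF", "WA", "PT+EN", "WA+EN")


def estimate_weights(method: str, train: FeatureMatrix, outcome,
                     covariates: pd.DataFrame, seed: int = 0,
                     config: dict | None = None) -> WeightSet:
    """Dispatch a method tag to its estimator on the training partition."""
    cfg = dict(config or {})
    if method == "PT":
        return compose(("PT",), train, outcome, covariates, seed, cfg)
    if method == "PT+EN":
        return compose(("PT", "EN"), train, outcome, covariates, seed, cfg)
    if method == "WA+EN":
        return compose(("WA", "EN"), train, outcome, covariates, seed, cfg)
    if method == "EN":
        return fit_ordinal_elasticnet(
            train, outcome, covariates, alpha_mix=cfg.get("alpha_mix", 0.5),
            n_lambda=cfg.get("n_lambda", 50),
            lambda_min_ratio=cfg.get("lambda_min_ratio", 1e-4),
            cv_folds=cfg.get("cv_folds", 5), seed=seed,
            maxiter=cfg.get("en_maxiter", 400))
    if method == "BO":
        return fit_ordinal_boosting(
            train, outcome, covariates, nu=cfg.get("nu", 0.1),
            mstop=cfg.get("mstop", 500),
            val_fraction=cfg.get("val_fraction", 0.25), seed=seed)
    if method == "RF":
        return fit_rf_vim(train, outcome, covariates,
                          n_trees=cfg.get("n_trees", 1000), seed=seed,
                          max_features=cfg.get("max_features", "sqrt"))
    if method == "WA":
        return cross_leverage_screen(
            train, outcome, window=cfg.get("window"), stride=cfg.get("stride"),
            q=cfg.get("q", 5), rank_r=cfg.get("rank_r"), seed=seed)
    if method == "threshold":
        return threshold_select(train, outcome, covariates,
                                alpha=cfg.get("alpha", 0.05), seed=seed)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
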