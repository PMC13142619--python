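"""Seeded iteration harness: repeated splits, aggregation, sensitivity runs.

One iteration = one seed: split the samples in half, estimate weights with
each requested method on the training half of each layer, score the test
half, and evaluate single-, multi- and joint-PS proportional-odds models.
Across seeds the harness aggregates the median partial R^2, the mean number
of selected features, and the count of significant iterations, and derives
stability feature lists (selected in at least ``min_count`` of the seeds).

A single split per seed is drawn over the union of sample ids; each layer
uses its own samples' intersection with that split, and joint/multi models
are evaluated on the samples observed in both layers.  Per-method random
number streams are derived independently from the iteration seed so methods
do not perturb each other's randomness.

When an output directory is given every weight set and evaluation row is
persisted as TSV and completed seed x method cells are skipped on re-run.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import FeatureMatrix, MultiOmicsDataset, covariate_design
from .preprocess import impute_missing, split_samples, standardize
from .scoring import ScoreVector, compute_ps, evaluate
from .selection import WeightSet, estimate_weights

__all__ = ["IterationSummary", "PipelineResult", "run_pipeline",
           "stability_features", "sensitivity", "method_seed"]

log = logging.getLogger("psomics.harness")

_FLOAT_FMT = "%.12g"

EVAL_COLUMNS = ["outcome", "method", "scope", "seed", "K", "partial_r2",
                "lrt_stat", "lrt_df", "lrt_p", "significant"]


@dataclass
class IterationSummary:
    """Aggregated per-seed results for one method x scope."""

    method: str
    scope: str              # layer name or model form
    outcome_kind: str
    rows: pd.DataFrame      # one row per successful seed (EVAL_COLUMNS)
    n_seeds: int            # seeds attempted
    n_failed: int = 0

    @property
    def median_r2(self) -> float:
        return float(self.rows["partial_r2"].median()) if len(self.rows) else np.nan

    @property
    def mean_k(self) -> float:
        return float(self.rows["K"].mean()) if len(self.rows) else np.nan

    @property
    def n_significant(self) -> int:
        return int(self.rows["significant"].sum())

    def summary_row(self) -> dict:
        return {"outcome": self.outcome_kind, "method": self.method,
                "scope": self.scope, "median_r2": self.median_r2,
                "mean_k": self.mean_k, "n_significant": self.n_significant,
                "n_iterations": self.n_seeds, "n_failed": self.n_failed}


@dataclass
class PipelineResult:
    """Everything a multi-seed run produced."""

    summaries: dict                 # (method, scope) -> IterationSummary
    weights: dict                   # (method, layer, seed) -> WeightSet
    evals: pd.DataFrame             # all per-seed evaluation rows
    seeds: list = field(default_factory=list)

    def summary(self, method: str, scope: str) -> IterationSummary:
        return self.summaries[(method, scope)]

    def weight_sets(self, method: str, layer: str) -> list[WeightSet]:
        return [w for (m, l, s), w in sorted(self.weights.items(),
                                             key=lambda kv: str(kv[0]))
                if m == method and l == layer]

    def summary_frame(self) -> pd.DataFrame:
        rows = [s.summary_row() for s in self.summaries.values()]
        return pd.DataFrame(rows).sort_values(["method", "scope"],
                                              ignore_index=True)


def method_seed(seed: int, method: str, layer: str) -> int:
    """Independent per-component substream seed below 2^31 (process-stable)."""
    key = [seed, zlib.crc32(method.encode()), zlib.crc32(layer.encode())]
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2 ** 31))


def _prepare_layer(fm: FeatureMatrix, split, scope: str, seed: int,
                   impute_kw: dict | None = None) -> FeatureMatrix:
    """Restrict the split to the layer's samples, impute and standardize."""
    ids = set(fm.sample_ids)
    sub = type(split)(seed=split.seed, fraction=split.fraction,
                      train_ids=[s for s in split.train_ids if s in ids],
                      test_ids=[s for s in split.test_ids if s in ids])
    m = fm.subset_samples(sub.train_ids + sub.test_ids)
    if m.has_missing:
        m = impute_missing(m, scope=scope if scope == "global" else "train-fitted",
                           split=sub, seed=method_seed(seed, "impute", fm.layer),
                           **(impute_kw or {}))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m, _ = standardize(m, sub)
    return m, sub


def _combined(dnam_std: FeatureMatrix, metab_std: FeatureMatrix,
              shared) -> FeatureMatrix:
    data = pd.concat([dnam_std.data.loc[shared], metab_std.data.loc[shared]],
                     axis=1)
    return FeatureMatrix(data, "combined")


def _cell_paths(out_dir: Path, method: str, seed: int, layers) -> dict:
    return {
        "evals": out_dir / "results" / "cells" / f"{method}_{seed}.tsv",
        "weights": {layer: out_dir / "weights" / f"{method}_{layer}_{seed}.tsv"
                    for layer in layers},
    }


def _write_weights(ws: WeightSet, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df = ws.to_frame().sort_values("feature_id", ignore_index=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _read_weights(path: Path, method: str, layer: str, seed: int) -> WeightSet:
    df = pd.read_csv(path, sep="\t")
    w = pd.Series(df["weight"].to_numpy(),
                  index=pd.Index(df["feature_id"], name="feature_id"),
                  name="weight")
    return WeightSet(method, layer, w, seed=seed)


def run_iteration(dataset: MultiOmicsDataset, methods, layers, seed: int,
                  train_fraction: float = 0.5, scope: str = "train-fitted",
                  method_config: dict | None = None,
                  ) -> tuple[list[dict], dict[tuple, WeightSet], dict[tuple, ScoreVector]]:
    """Run one seed: returns (eval rows, weight sets, test score vectors)."""
    cfg = method_config or {}
    all_ids = sorted(dataset.covariates.index)
    split = split_samples(all_ids, seed=seed, fraction=train_fraction)
    design = covariate_design(dataset.covariates)

    prepared = {}
    for layer in ("dnam", "metabolome"):
        fm = dataset.dnam if layer == "dnam" else dataset.metab
        if fm is not None:
            prepared[layer] = _prepare_layer(fm, split, scope, seed)

    if "combined" in layers:
        if len(prepared) < 2:
            raise ValueError("combined layer requires both omics layers")
        shared = dataset.shared_samples
        dn, dn_sub = prepared["dnam"]
        mb, _ = prepared["metabolome"]
        strain = sorted(set(split.train_ids) & set(shared))
        stest = sorted(set(split.test_ids) & set(shared))
        comb = _combined(dn, mb, strain + stest)
        comb_sub = type(split)(seed=seed, fraction=train_fraction,
                               train_ids=strain, test_ids=stest)
        prepared["combined"] = (comb, comb_sub)

    rows, weight_sets, scores = [], {}, {}
    for method in methods:
        for layer in layers:
            if layer not in prepared:
                continue
            fm, sub = prepared[layer]
            mcfg = {**cfg.get("all", {}), **cfg.get(method, {})}
            ws = estimate_weights(method, fm.subset_samples(sub.train_ids),
                                  dataset.outcome.subset(sub.train_ids),
                                  design.loc[sub.train_ids],
                                  seed=method_seed(seed, method, layer),
                                  config=mcfg)
            weight_sets[(method, layer)] = ws
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                sv = compute_ps(fm.subset_samples(sub.test_ids), ws)
            scores[(method, layer)] = sv
            form = "multi" if layer == "combined" else "single"
            test_outcome = dataset.outcome.subset(sub.test_ids)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                ev = evaluate(form, test_outcome, design.loc[sub.test_ids],
                              **({"ps_combined": sv} if form == "multi"
                                 else {"ps_dnam" if layer == "dnam"
                                       else "ps_metab": sv}))
            rows.append(ev.row(outcome="", method=method, seed=seed,
                               scope=layer))
        # joint models need both single-layer scores
        if {"dnam", "metabolome"} <= set(prepared) and \
                {"dnam", "metabolome"} <= {l for (m, l) in scores if m == method}:
            sv_d = scores[(method, "dnam")]
            sv_m = scores[(method, "metabolome")]
            shared_test = sv_d.sample_ids.intersection(sv_m.sample_ids)
            if len(shared_test) >= 4:
                y_t = dataset.outcome.subset(shared_test)
                zt = design.loc[shared_test]
                svd = ScoreVector(sv_d.scores.loc[shared_test], sv_d.source)
                svm = ScoreVector(sv_m.scores.loc[shared_test], sv_m.source)
                for form in ("joint", "joint_interaction"):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        ev = evaluate(form, y_t, zt, ps_dnam=svd, ps_metab=svm)
                    rows.append(ev.row(outcome="", method=method, seed=seed,
                                       scope=form))
    return rows, weight_sets, scores


def run_pipeline(dataset: MultiOmicsDataset, outcome_kind: str, methods,
                 layers, seeds, out_dir=None, train_fraction: float = 0.5,
                 scope: str = "train-fitted", method_config: dict | None = None,
                 ) -> PipelineResult:
    """Run the full multi-seed pipeline and aggregate.

    The result's ``summaries`` map (method, scope) to an IterationSummary,
    where scope is a layer for single/multi models or a joint form.  With
    ``out_dir``, weight sets and evaluations are persisted and completed
    cells are resumed from disk.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "results").mkdir(parents=True, exist_ok=True)
        (out / "weights").mkdir(exist_ok=True)
        logging.basicConfig()
    all_rows: list[dict] = []
    failures: dict[tuple, int] = {}
    weight_store: dict[tuple, WeightSet] = {}

    for seed in seeds:
        for method in methods:
            paths = (_cell_paths(out, method, seed, layers) if out is not None
                     else None)
            if paths is not None and paths["evals"].exists():
                cell = pd.read_csv(paths["evals"], sep="\t")
                all_rows.extend(cell.to_dict("records"))
                for layer, wp in paths["weights"].items():
                    if wp.exists():
                        weight_store[(method, layer, seed)] = _read_weights(
                            wp, method, layer, seed)
                log.info("resume: skipping %s seed %s", method, seed)
                continue
            try:
                rows, wsets, _ = run_iteration(
                    dataset, [method], layers, seed,
                    train_fraction=train_fraction, scope=scope,
                    method_config=method_config)
            except Exception as exc:  # failed cells are recorded, not fatal
                log.warning("cell failed: %s seed %s: %s", method, seed, exc)
                for layer in layers:
                    failures[(method, layer)] = failures.get((method, layer), 0) + 1
                continue
            for r in rows:
                r["outcome"] = outcome_kind
                for key, v in r.items():
                    # normalize to the TSV precision so a resumed run
                    # aggregates bit-identical values
                    if isinstance(v, float):
                        r[key] = float(f"{v:.12g}")
            all_rows.extend(rows)
            for (m, layer), ws in wsets.items():
                weight_store[(m, layer, seed)] = ws
            if paths is not None:
                for layer, wp in paths["weights"].items():
                    if (method, layer) in wsets:
                        _write_weights(wsets[(method, layer)], wp)
                paths["evals"].parent.mkdir(parents=True, exist_ok=True)
                pd.DataFrame([r for r in rows], columns=EVAL_COLUMNS).to_csv(
                    paths["evals"], sep="\t", index=False, float_format=_FLOAT_FMT)

    evals = pd.DataFrame(all_rows, columns=EVAL_COLUMNS)
    summaries: dict[tuple, IterationSummary] = {}
    for (method, model_scope), grp in evals.groupby(["method", "scope"], sort=True):
        summaries[(method, model_scope)] = IterationSummary(
            method=method, scope=model_scope, outcome_kind=outcome_kind,
            rows=grp.sort_values("seed", ignore_index=True),
            n_seeds=len(list(seeds)),
            n_failed=failures.get((method, model_scope), 0))
    result = PipelineResult(summaries=summaries, weights=weight_store,
                            evals=evals, seeds=list(seeds))
    if out is not None:
        evals.sort_values(["method", "scope", "seed"], ignore_index=True).to_csv(
            out / "results" / "evals.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
        result.summary_frame().to_csv(
            out / "results" / "summary.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
        cells = {(m, l) for (m, l, _s) in weight_store}
        for method, layer in sorted(cells):
            sets = result.weight_sets(method, layer)
            for mc in (1, 2, 3):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    write_stability(out, method, layer,
                                    stability_features(sets, mc), mc)
    return result


def stability_features(weight_sets, min_count: int) -> pd.DataFrame:
    """Features selected in at least ``min_count`` of the supplied seeds.

    ``weight_sets`` is an iterable of WeightSet (same method/layer across
    seeds).  Returns a table (layer, feature_id, times_selected) ordered by
    count descending then id ascending.
    """
    ws = list(weight_sets)
    if not ws:
        raise ValueError("need at least one weight set")
    n = len(ws)
    if min_count > n:
        warnings.warn(f"min_count={min_count} exceeds the {n} supplied seeds; "
                      "empty list", RuntimeWarning)
    counts: dict[tuple, int] = {}
    for w in ws:
        for fid in w.weights.index:
            counts[(w.layer, fid)] = counts.get((w.layer, fid), 0) + 1
    rows = [{"layer": layer, "feature_id": fid, "times_selected": c}
            for (layer, fid), c in counts.items() if c >= min_count]
    df = pd.DataFrame(rows, columns=["layer", "feature_id", "times_selected"])
    return df.sort_values(["times_selected", "feature_id"],
                          ascending=[False, True], ignore_index=True)


def write_stability(out_dir, method: str, layer: str, table: pd.DataFrame,
                    min_count: int) -> Path:
    path = Path(out_dir) / "stability" / f"{method}_{layer}_min{min_count}.tsv"
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path


def sensitivity(dataset: MultiOmicsDataset, mode: str, outcome_kind: str,
                methods, layers, seeds, out_dir=None, n_iterations: int = 100,
                **kw) -> PipelineResult:
    """The two sensitivity analyses.

    ``complete-case`` reruns the single-layer pipelines restricted to the
    samples observed in every layer; ``n_iterations`` reruns the main
    pipeline with an expanded seed list (``seeds[0] .. seeds[0]+n-1`` when a
    base list of seeds is given).
    """
    if mode == "complete-case":
        shared = dataset.shared_samples
        if len(shared) == 0:
            raise ValueError("no samples with complete multi-omics data")
        sub = MultiOmicsDataset(
            dataset.dnam.subset_samples(shared) if dataset.dnam is not None else None,
            dataset.metab.subset_samples(shared) if dataset.metab is not None else None,
            dataset.covariates.loc[shared],
            dataset.outcome.subset(shared))
        res = run_pipeline(sub, outcome_kind, methods,
                           [l for l in layers if l != "combined"], seeds,
                           out_dir=out_dir, **kw)
    elif mode == "n_iterations":
        base = list(seeds)[0] if len(list(seeds)) else 0
        long_seeds = [base + i for i in range(n_iterations)]
        res = run_pipeline(dataset, outcome_kind, methods, layers, long_seeds,
                           out_dir=out_dir, **kw)
    else:
        raise ValueError(f"unknown sensitivity mode {mode!r}")
    for s in res.summaries.values():
        s.rows.attrs["sensitivity_mode"] = mode
    return res
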