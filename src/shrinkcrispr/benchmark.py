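"""Scoring hit calls against simulation truth: confusion matrices,
accuracy measures and vertically averaged ROC curves.

``run_benchmark`` drives the full comparison: for every scenario
(design, effect size) it simulates screens, analyzes each with the
mixed-model pipeline and/or the drugZ-style baseline, scores the calls
against the generator's truth labels and aggregates mean and standard
deviation across datasets.  ROC curves are averaged vertically: the mean
true-positive rate at a fixed grid of false-positive rates.

Rate conventions for empty denominators (constant in Delta=0 scenarios,
recorded in the result metadata): precision = 1 when nothing is called,
sensitivity = 1 when no effect genes exist, specificity = 1 when no null
genes exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import baselines
from .api import ShrinkCrisprModel
from .simulate import SimulationConfig, simulate_screen

__all__ = ["BenchmarkResult", "confusion", "roc_curve", "average_roc",
           "run_benchmark"]

FPR_GRID = np.round(np.arange(0.0, 1.0001, 0.01), 2)


@dataclass(frozen=True)
class BenchmarkResult:
    """Aggregated per-scenario metrics and averaged ROC curves."""

    metrics: pd.DataFrame   # design, delta, method, metric mean/sd columns
    roc: pd.DataFrame       # design, delta, method, fpr, tpr
    n_datasets: int
    seed: int
    failures: pd.DataFrame = field(default_factory=pd.DataFrame)
    conventions: str = ("precision=1 when no calls; sensitivity=1 when no "
                        "effect genes; specificity=1 when no null genes")


def confusion(hits: set, truth: pd.Series):
    """(TP, FP, TN, FN) of a hit set against boolean truth labels."""
    truth = truth.astype(bool)
    unknown = set(hits) - set(truth.index)
    if unknown:
        raise ValueError(f"hit gene {sorted(unknown)[0]!r} absent from truth")
    is_hit = truth.index.isin(hits)
    t = truth.to_numpy()
    tp = int(np.sum(is_hit & t))
    fp = int(np.sum(is_hit & ~t))
    fn = int(np.sum(~is_hit & t))
    tn = int(np.sum(~is_hit & ~t))
    return tp, fp, tn, fn


def _rates(tp, fp, tn, fn):
    sens = tp / (tp + fn) if (tp + fn) else 1.0
    spec = tn / (tn + fp) if (tn + fp) else 1.0
    prec = tp / (tp + fp) if (tp + fp) else 1.0
    acc = (tp + tn) / (tp + fp + tn + fn)
    return {"sensitivity": sens, "specificity": spec, "precision": prec,
            "recall": sens, "accuracy": acc}


def roc_curve(scores: pd.Series, truth: pd.Series):
    """Full-sweep ROC from an ordering statistic (smaller = stronger call).

    Ties are grouped: all genes sharing a score enter together.  Returns
    arrays (fpr, tpr) starting at (0, 0) and ending at (1, 1).
    """
    truth = truth.astype(bool)
    scores = scores.reindex(truth.index)
    if scores.isna().any():
        raise ValueError("scores missing for some genes in truth")
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: truth is all-null or all-effect")
    df = pd.DataFrame({"score": scores.to_numpy(), "t": truth.to_numpy()})
    grouped = df.groupby("score", sort=True)["t"].agg(["sum", "count"])
    tp = np.cumsum(grouped["sum"].to_numpy())
    calls = np.cumsum(grouped["count"].to_numpy())
    fp = calls - tp
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    if tpr[-1] != 1.0 or fpr[-1] != 1.0:
        tpr = np.append(tpr, 1.0)
        fpr = np.append(fpr, 1.0)
    return fpr, tpr


def average_roc(curves, grid=FPR_GRID):
    """Vertical average of step ROC curves on a fixed FPR grid."""
    tprs = []
    for fpr, tpr in curves:
        tprs.append(np.interp(grid, fpr, tpr))
    mean_tpr = np.mean(tprs, axis=0)
    return grid, mean_tpr


def _analyze_shrinkcrispr(sim, lfdr_threshold, quantile_normalize):
    model = ShrinkCrisprModel(sim.screen, sim.sheet, sim.controls,
                              quantile_normalize=quantile_normalize)
    res = model.fit(lfdr_threshold=lfdr_threshold)
    t = res.table.set_index("gene")
    scores = t["lfdr"].reindex(sim.truth.index)
    # excluded genes (if any) score as never-called
    scores = scores.fillna(1.0)
    hits = res.hit_genes() & set(sim.truth.index)
    return hits, scores


def _library_screen(sim):
    """The count screen restricted to library (non-control) guides.

    The assay controls anchor the lethality scale for the mixed-model
    pipeline; neither method tests them, and the baseline is run without
    them so its gene-level re-scaling reflects the library only.
    """
    ctrl = sim.controls.positive_genes | sim.controls.negative_genes
    screen = sim.screen
    keep = [i for i, g in enumerate(screen.guide_ids)
            if screen.gene_of_guide[g] not in ctrl]
    gids = tuple(screen.guide_ids[i] for i in keep)
    from .io import CountScreen
    return CountScreen(
        guide_ids=gids,
        gene_of_guide={g: screen.gene_of_guide[g] for g in gids},
        counts=screen.counts[keep], sample_ids=screen.sample_ids)


def _analyze_drugz(sim, level, adjusted):
    res = baselines.drugz_scores(_library_screen(sim), sim.sheet)
    t = res.table.set_index("gene")
    scores = t["pvalue"].reindex(sim.truth.index).fillna(1.0)
    hits = baselines.call_baseline_hits(res, level=level, adjusted=adjusted) \
        & set(sim.truth.index)
    return hits, scores


def run_benchmark(scenarios, n_datasets: int = 10,
                  methods=("shrinkcrispr", "drugz"), seed: int = 0,
                  lfdr_threshold: float = 0.05, p_level: float = 0.05,
                  adjusted: bool = False, quantile_normalize: bool = False,
                  base_config: SimulationConfig | None = None,
                  ) -> BenchmarkResult:
    """Simulate, analyze and score every scenario with every method.

    ``scenarios`` is an iterable of ``(design, delta)`` pairs.  Each
    dataset's generator seed derives deterministically from ``seed`` and
    the (scenario, dataset) indices, so any single dataset can be
    regenerated in isolation and aggregates do not depend on iteration
    order.
    """
    methods = tuple(methods)
    unknown = set(methods) - {"shrinkcrispr", "drugz"}
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    base = base_config if base_config is not None else SimulationConfig()
    rows, roc_rows, failures = [], [], []
    for s_idx, (design, delta) in enumerate(scenarios):
        per_method = {m: [] for m in methods}
        curves = {m: [] for m in methods}
        for d_idx in range(n_datasets):
            ds_seed = int(np.random.SeedSequence(
                entropy=seed, spawn_key=(s_idx, d_idx)).generate_state(1)[0]
                % (2 ** 31))
            config = replace(base, design=design, delta=float(delta),
                             seed=ds_seed)
            sim = simulate_screen(config)
            for method in methods:
                try:
                    if method == "shrinkcrispr":
                        hits, scores = _analyze_shrinkcrispr(
                            sim, lfdr_threshold, quantile_normalize)
                    else:
                        hits, scores = _analyze_drugz(sim, p_level, adjusted)
                except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                    warnings.warn(
                        f"{method} failed on scenario ({design}, {delta}) "
                        f"dataset {d_idx}: {exc}")
                    failures.append((design, delta, method, d_idx, str(exc)))
                    continue
                tp, fp, tn, fn = confusion(hits, sim.truth)
                rec = {"TP": tp, "FP": fp, "TN": tn, "FN": fn,
                       **_rates(tp, fp, tn, fn)}
                per_method[method].append(rec)
                if sim.truth.any() and not sim.truth.all():
                    curves[method].append(roc_curve(scores, sim.truth))
        for method in methods:
            recs = per_method[method]
            if not recs:
                continue
            df = pd.DataFrame(recs)
            row = {"design": design, "delta": float(delta), "method": method,
                   "n_datasets": len(recs)}
            for col in df.columns:
                row[f"{col}_mean"] = float(df[col].mean())
                row[f"{col}_sd"] = float(df[col].std(ddof=1)) if len(df) > 1 else 0.0
            rows.append(row)
            if curves[method]:
                grid, mean_tpr = average_roc(curves[method])
                for f, t in zip(grid, mean_tpr):
                    roc_rows.append({"design": design, "delta": float(delta),
                                     "method": method, "fpr": f, "tpr": t})
    return BenchmarkResult(
        metrics=pd.DataFrame(rows),
        roc=pd.DataFrame(roc_rows),
        n_datasets=n_datasets, seed=seed,
        failures=pd.DataFrame(
            failures, columns=["design", "delta", "method", "dataset", "error"]),
    )
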