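"""Classification metrics, cross-validation, multi-run outcome tables and the
statistical validation suite (Shapiro-Wilk normality, paired Wilcoxon).

The metric set is the standard confusion-matrix five: accuracy, recall
(sensitivity), specificity, precision and F1.  Zero-denominator ratios are
returned as 0 with an explicit flag instead of NaN so that composite scores
built from them stay bounded.  The statistical tests delegate to scipy.stats
and are validated against independent reference implementations in the test
suite.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

NORMAL_LABEL = "normal"


def _is_positive(labels: Sequence[str]) -> np.ndarray:
    """Disease is the positive class; any non-normal label counts as disease."""
    return np.asarray([str(l) != NORMAL_LABEL for l in labels], dtype=bool)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(labels: Sequence[str], predictions: Sequence[str]) -> ConfusionCounts:
    """Exact binary confusion counts; ternary labels collapse to normal-vs-disease."""
    if len(labels) != len(predictions):
        raise ValueError("labels and predictions must have equal length")
    y = _is_positive(labels)
    p = _is_positive(predictions)
    return ConfusionCounts(
        tp=int(np.sum(y & p)),
        fp=int(np.sum(~y & p)),
        tn=int(np.sum(~y & ~p)),
        fn=int(np.sum(y & ~p)),
    )


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    recall: float
    specificity: float
    precision: float
    f1: float
    undefined: tuple[str, ...] = ()  # ratios whose denominator was zero

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "undefined": list(self.undefined),
        }


def metrics(counts: ConfusionCounts) -> MetricSet:
    """The five confusion-matrix measures; zero denominators give flagged 0."""
    if counts.total == 0:
        raise ValueError("no scored records")
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = (counts.tp + counts.tn) / counts.total
    recall = ratio(counts.tp, counts.tp + counts.fn, "recall")
    specificity = ratio(counts.tn, counts.tn + counts.fp, "specificity")
    precision = ratio(counts.tp, counts.tp + counts.fp, "precision")
    f1 = ratio(2.0 * precision * recall, precision + recall, "f1")
    return MetricSet(accuracy, recall, specificity, precision, f1, tuple(undefined))


# ---------------------------------------------------------------------------
# Cross-validation and split sweeps
# ---------------------------------------------------------------------------


def stratified_indices(
    labels: Sequence[str], k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """k disjoint, label-stratified folds covering all indices exactly once."""
    labels = np.asarray(labels)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls!r} has fewer than k={k} members")
        idx = idx[rng.permutation(len(idx))]
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f)) for f in folds]


TrainPredictFn = Callable[[pd.DataFrame, pd.DataFrame], Sequence[str]]


def kfold(
    cohort: pd.DataFrame, k: int, train_fn: TrainPredictFn, seed: int
) -> tuple[list[MetricSet], dict]:
    """Stratified k-fold CV.  ``train_fn(train_df, val_df)`` returns val labels.

    Returns per-fold metric sets and a mean/SD summary (SD with n-1).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = stratified_indices(cohort["label"].tolist(), k, rng)
    per_fold = []
    for val_idx in folds:
        val = cohort.iloc[val_idx]
        train = cohort.drop(cohort.index[val_idx])
        preds = train_fn(train, val)
        per_fold.append(metrics(confusion(val["label"].tolist(), preds)))
    summary = {}
    for name in ("accuracy", "recall", "specificity", "precision", "f1"):
        vals = np.array([getattr(m, name) for m in per_fold])
        summary[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
    return per_fold, summary


def train_test_split_stratified(
    cohort: pd.DataFrame, train_fraction: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One stratified split; class ratios preserved to within rounding."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    labels = cohort["label"].to_numpy()
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[:n_train].tolist())
    mask = np.zeros(len(cohort), dtype=bool)
    mask[train_idx] = True
    return cohort.iloc[mask].copy(), cohort.iloc[~mask].copy()


def split_sweep(
    cohort: pd.DataFrame,
    ratios: Sequence[float],
    train_fn: TrainPredictFn,
    seed: int,
) -> list[dict]:
    """Per training-fraction: one stratified split, one run, metrics + wall time.

    Build time is measured and reported, never asserted — it is hardware
    dependent.
    """
    rows = []
    for frac in ratios:
        train, test = train_test_split_stratified(cohort, frac, seed)
        start = time.perf_counter()
        preds = train_fn(train, test)
        build_seconds = time.perf_counter() - start
        rows.append(
            {
                "train_fraction": float(frac),
                "metrics": metrics(confusion(test["label"].tolist(), preds)),
                "build_seconds": build_seconds,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# Multi-run outcome statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunOutcomes:
    """Order statistics and moments of one scalar metric over repeated runs."""

    best: float
    worst: float
    mean: float
    median: float
    sd: float
    variance: float
    n_runs: int


def multirun_outcomes(samples: Sequence[float], maximize: bool = True) -> RunOutcomes:
    """Best/worst/mean/median/SD/variance over R >= 2 runs (SD uses n-1)."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two runs")
    sd = float(x.std(ddof=1))
    best = float(x.max() if maximize else x.min())
    worst = float(x.min() if maximize else x.max())
    return RunOutcomes(
        best=best,
        worst=worst,
        mean=float(x.mean()),
        median=float(np.median(x)),
        sd=sd,
        variance=sd**2,
        n_runs=int(x.size),
    )


# ---------------------------------------------------------------------------
# Statistical validation
# ---------------------------------------------------------------------------


def shapiro_wilk(sample: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p for 3 <= n <= 5000 non-constant samples."""
    x = np.asarray(sample, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample")
    res = _st.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Paired signed-rank test on a-b; zero differences dropped, mid-ranks for ties.

    Exact null distribution for n <= 25 surviving pairs (no ties among
    |differences|), normal approximation otherwise.  ``alternative`` is
    "two-sided", "greater" (a tends larger) or "less".
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("all paired differences are zero")
    if nz.size < 6:
        raise ValueError("need at least 6 non-zero differences")
    method = "exact" if (nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size) else "approx"
    res = _st.wilcoxon(nz, zero_method="wilcox", alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Optimizer comparison (convergence + statistical validation)
# ---------------------------------------------------------------------------


@dataclass
class ComparisonReport:
    variants: list[str]
    final_fitness: dict  # variant -> list of final best fitness, one per seed
    traces: dict  # variant -> list of best-so-far traces
    shapiro: dict  # variant -> {"W": float, "p": float}
    wilcoxon: dict  # "a_vs_b" -> {"statistic", "p", "alternative"}
    seeds: list[int]
    complete: bool = True

    def trace_frame(self) -> pd.DataFrame:
        """Plot-ready long-format convergence traces."""
        rows = []
        for variant, traces in self.traces.items():
            for seed, trace in zip(self.seeds, traces):
                for it, val in enumerate(trace):
                    rows.append(
                        {"variant": variant, "seed": seed, "iteration": it, "best_fitness": val}
                    )
        return pd.DataFrame(rows)


def compare_optimizers(
    variants: Sequence[str],
    objective: Callable[[np.ndarray], float],
    bounds,
    n_seeds: int = 20,
    population: int = 20,
    max_iterations: int = 300,
    base_seed: int = 0,
    alternative: str = "two-sided",
) -> ComparisonReport:
    """Run each variant on identical seeds; test normality and paired differences.

    Variants share the seed list so final-fitness samples are paired; the
    Wilcoxon block covers every ordered variant pair.
    """
    from .chaos_opt import OptimizerConfig, optimize

    if len(variants) < 2:
        raise ValueError("need at least two variants")
    if n_seeds < 6:
        raise ValueError("need at least 6 seeds for the paired test")
    seeds = [base_seed + i for i in range(n_seeds)]
    finals: dict[str, list[float]] = {v: [] for v in variants}
    traces: dict[str, list[np.ndarray]] = {v: [] for v in variants}
    for variant in variants:
        for seed in seeds:
            cfg = OptimizerConfig(
                population=population,
                max_iterations=max_iterations,
                variant=variant,
                seed=seed,
            )
            res = optimize(objective, bounds, cfg)
            finals[variant].append(res.best_fitness)
            traces[variant].append(res.trace)

    shapiro = {}
    for v in variants:
        x = np.asarray(finals[v])
        if np.ptp(x) == 0:  # a constant sample has no testable normality
            shapiro[v] = {"W": float("nan"), "p": float("nan")}
        else:
            w, p = shapiro_wilk(x)
            shapiro[v] = {"W": w, "p": p}

    wilcoxon = {}
    for i, va in enumerate(variants):
        for vb in variants[i + 1:]:
            key = f"{va}_vs_{vb}"
            try:
                stat, p = wilcoxon_signed_rank(finals[va], finals[vb], alternative)
            except ValueError:
                stat, p = float("nan"), 1.0  # identical samples: no evidence of difference
            wilcoxon[key] = {"statistic": stat, "p": p, "alternative": alternative}

    return ComparisonReport(
        variants=list(variants),
        final_fitness={v: list(map(float, finals[v])) for v in variants},
        traces={v: [t.tolist() for t in traces[v]] for v in variants},
        shapiro=shapiro,
        wilcoxon=wilcoxon,
        seeds=seeds,
    )


def noninferiority_wilcoxon(
    candidate: Sequence[float],
    reference: Sequence[float],
    margin: float,
    alpha: float = 0.05,
) -> dict:
    """Margin-based non-inferiority on paired minimization results.

    Tests H1: median(candidate - reference) < margin with a one-sided
    signed-rank test on the shifted differences; non-inferior when p < alpha.
    """
    c = np.asarray(candidate, dtype=float)
    r = np.asarray(reference, dtype=float)
    stat, p = wilcoxon_signed_rank(c - margin, r, alternative="less")
    return {"statistic": stat, "p": p, "margin": margin, "noninferior": bool(p < alpha)}
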